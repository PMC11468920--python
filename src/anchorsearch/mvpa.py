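"""Linear decoding of beta patterns and the classifier-information score.

Decoding uses a hard/soft-margin linear support vector machine (C = 1) per
hemisphere.  Performance is summarized by *classifier information*: each test
pattern's signed distance to the decision boundary is z-scored over the test
set and multiplied by the true label (±1), then averaged —

    information = (1/n) Σ_i zd_i · l_i

a continuous analogue of decoding accuracy.  Three schemes are provided:
leave-one-run-out decoding of the target category, of the associated anchor,
and a cross-scene generalization scheme that trains on one scene context's
anchor labels and tests on the other.  Because the target→anchor association
reverses across contexts, a *positive* cross-scene score indicates anchor
coding and a *negative* score indicates target coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from anchorsearch import design as _design


@dataclass
class LinearModel:
    """Trained linear separator: decision value w·x + b."""

    weights: np.ndarray
    bias: float


def train_linear(train_patterns, train_labels, C: float = 1.0) -> LinearModel:
    """Fit a max-margin linear SVM (deterministic for fixed input order)."""
    X = np.asarray(train_patterns, dtype=float)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("train_patterns must be (n_patterns, n_voxels) with >= 1 voxel")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    # sklearn orders classes ascending; coef_ is for the +1-vs-(-1) problem
    w = svc.coef_[0].copy()
    b = float(svc.intercept_[0])
    return LinearModel(weights=w, bias=b)


def decision_values(model: LinearModel, test_patterns) -> np.ndarray:
    """Signed geometric distances to the boundary: (w·x + b)/‖w‖.

    Positive distances vote for class +1.  Scaling by ‖w‖ makes the units
    input-space distance; the information score is invariant to this.
    """
    X = np.asarray(test_patterns, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.weights.size:
        raise ValueError("voxel dimension mismatch between model and test patterns")
    nrm = np.linalg.norm(model.weights)
    if nrm == 0:
        return np.zeros(X.shape[0])
    return (X @ model.weights + model.bias) / nrm


def classifier_information(distances, labels) -> float:
    """Mean of z-scored distance-to-bound times the true label.

    Distances are z-scored over the n test values (population SD); a zero SD
    returns 0 by convention.  Requires n ≥ 2.
    """
    d = np.asarray(distances, dtype=float)
    l = np.asarray(labels, dtype=float)
    if d.ndim != 1 or d.size != l.size:
        raise ValueError("distances and labels must be 1-D and equal length")
    if d.size < 2:
        raise ValueError("need at least 2 test patterns")
    if not set(np.unique(l)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    sd = d.std()
    if sd == 0:
        return 0.0
    return float(np.mean((d - d.mean()) / sd * l))


def accuracy_score(distances, labels) -> float:
    """Fraction of correctly signed distances; ties at d = 0 count 0.5."""
    d = np.asarray(distances, dtype=float)
    l = np.asarray(labels, dtype=float)
    if d.size != l.size or d.size == 0:
        raise ValueError("distances and labels must be non-empty and equal length")
    correct = np.where(d == 0, 0.5, (np.sign(d) == l).astype(float))
    return float(correct.mean())


def target_label(target: str, context: str, association=None) -> int:
    return 1 if target == _design.TARGETS[0] else -1


def anchor_label(target: str, context: str, association) -> int:
    return 1 if association.anchor_for(target, context) == _design.ANCHORS[0] else -1


@dataclass(frozen=True)
class DecodingScheme:
    """A decoding problem: labeling rule plus train/test partition.

    ``fold`` is "loro" (leave-one-run-out) or "cross_scene" (train on one
    scene context, test on the other, both directions averaged).
    """

    name: str
    label_fn: object
    fold: str


SCHEMES = {
    "target_loro": DecodingScheme("target_loro", target_label, "loro"),
    "anchor_loro": DecodingScheme("anchor_loro", anchor_label, "loro"),
    "anchor_cross_scene": DecodingScheme("anchor_cross_scene", anchor_label, "cross_scene"),
}


@dataclass
class DecodingResult:
    participant_id: object
    roi_name: str
    roi_size: int
    scheme: str
    info: float
    accuracy: float
    per_hemisphere: dict = field(default_factory=dict)


def _condition_labels(betas, scheme: DecodingScheme, association) -> np.ndarray:
    return np.array([scheme.label_fn(t, c, association) for t, c in betas.condition_labels])


def _decode_loro(betas, labels, C):
    # a condition missing from a run is encoded as NaN betas; such folds are
    # skipped with a warning
    n_runs, n_cond, nv = betas.values.shape
    usable = ~np.isnan(betas.values).any(axis=(1, 2))
    dists, labs = [], []
    for held in range(n_runs):
        if not usable[held]:
            warnings.warn(f"run {held} has a missing condition; fold skipped")
            continue
        train_runs = [r for r in range(n_runs) if r != held and usable[r]]
        Xtr = betas.values[train_runs].reshape(-1, nv)
        ytr = np.tile(labels, len(train_runs))
        model = train_linear(Xtr, ytr, C=C)
        d = decision_values(model, betas.values[held])
        dists.append(d)
        labs.append(labels)
    return np.concatenate(dists), np.concatenate(labs)


def _decode_cross_scene(betas, labels, C):
    ctx = np.array([c for _, c in betas.condition_labels])
    n_runs, _, nv = betas.values.shape
    infos, accs = [], []
    for train_ctx in _design.CONTEXTS:
        tr = np.where(ctx == train_ctx)[0]
        te = np.where(ctx != train_ctx)[0]
        if tr.size == 0 or te.size == 0:
            raise ValueError("cross-scene decoding needs both contexts")
        Xtr = betas.values[:, tr].reshape(-1, nv)
        ytr = np.tile(labels[tr], n_runs)
        Xte = betas.values[:, te].reshape(-1, nv)
        yte = np.tile(labels[te], n_runs)
        model = train_linear(Xtr, ytr, C=C)
        d = decision_values(model, Xte)
        infos.append(classifier_information(d, yte))
        accs.append(accuracy_score(d, yte))
    return float(np.mean(infos)), float(np.mean(accs))


def run_scheme(betas_by_hemisphere, scheme, association, C: float = 1.0,
               zscore_per_fold: bool = False, participant_id=None) -> DecodingResult:
    """Decode one participant's patterns under a scheme, averaging hemispheres.

    ``betas_by_hemisphere`` maps hemisphere name → BetaPatterns (a single
    BetaPatterns is accepted).  LORO pools test distances across the folds
    and computes the information score once on the pooled set (per-fold
    z-scoring available via ``zscore_per_fold``); cross-scene averages the
    two train/test directions.  Hemispheres are decoded separately and their
    scores averaged.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if not isinstance(betas_by_hemisphere, dict):
        betas_by_hemisphere = {betas_by_hemisphere.hemisphere: betas_by_hemisphere}
    per_hemi = {}
    for hemi, betas in betas_by_hemisphere.items():
        if betas.voxel_ids.size == 0:
            raise ValueError(f"empty ROI for hemisphere {hemi!r}")
        labels = _condition_labels(betas, scheme, association)
        if np.abs(labels.sum()) == labels.size:
            raise ValueError("labeling rule is degenerate: single class")
        if scheme.fold == "loro":
            if betas.n_runs < 2:
                raise ValueError("leave-one-run-out needs >= 2 runs")
            if zscore_per_fold:
                infos, accs = [], []
                n_runs = betas.n_runs
                for held in range(n_runs):
                    sub = [r for r in range(n_runs) if r != held]
                    Xtr = betas.values[sub].reshape(-1, betas.values.shape[2])
                    ytr = np.tile(labels, len(sub))
                    model = train_linear(Xtr, ytr, C=C)
                    d = decision_values(model, betas.values[held])
                    infos.append(classifier_information(d, labels))
                    accs.append(accuracy_score(d, labels))
                info, acc = float(np.mean(infos)), float(np.mean(accs))
            else:
                d, l = _decode_loro(betas, labels, C)
                info = classifier_information(d, l)
                acc = accuracy_score(d, l)
        elif scheme.fold == "cross_scene":
            info, acc = _decode_cross_scene(betas, labels, C)
        else:
            raise ValueError(f"unknown fold rule {scheme.fold!r}")
        per_hemi[hemi] = {"info": info, "accuracy": acc}
    info = float(np.mean([v["info"] for v in per_hemi.values()]))
    acc = float(np.mean([v["accuracy"] for v in per_hemi.values()]))
    any_betas = next(iter(betas_by_hemisphere.values()))
    return DecodingResult(participant_id=participant_id, roi_name=any_betas.roi_name,
                          roi_size=int(any_betas.voxel_ids.size), scheme=scheme.name,
                          info=info, accuracy=acc, per_hemisphere=per_hemi)


def results_to_frame(results) -> pd.DataFrame:
    """Long-format results table (one row per participant × ROI × scheme)."""
    rows = []
    for r in results:
        for hemi, v in (r.per_hemisphere or {"both": {"info": r.info, "accuracy": r.accuracy}}).items():
            rows.append((r.participant_id, r.roi_name, r.roi_size, hemi, r.scheme,
                         v["info"], v["accuracy"]))
        rows.append((r.participant_id, r.roi_name, r.roi_size, "mean", r.scheme,
                     r.info, r.accuracy))
    return pd.DataFrame(rows, columns=["participant", "roi", "roi_size", "hemisphere",
                                       "scheme", "info", "accuracy"])
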