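"""Synthetic data generator.

Emulates the statistical structure the analysis pipeline assumes, at the
voxel-pattern level (it stands in for preprocessed, GLM-estimated data):

- run-wise beta patterns per (target × scene context) condition containing
  additive multivariate codes for the associated anchor (the *same* pattern
  wherever that anchor is the associated one, across contexts), the target
  category and the scene context, plus i.i.d. Gaussian noise;
- localizer betas with target- and anchor-selective voxel subsets;
- fixation sequences whose first scene fixation lands on the associated
  anchor with a tunable guidance probability;
- present/absent responses from an equal-variance signal-detection model
  whose d′ increases with the participant's guidance.

Code patterns are random direction vectors scaled to unit per-voxel RMS
(Euclidean norm √n_voxels), so the ``*_amp`` amplitudes are per-voxel signal
standard deviations in the same units as ``noise_sd``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from anchorsearch import design as _design
from anchorsearch import gaze as _gaze
from anchorsearch import glm as _glm
from anchorsearch._rng import as_rng

CONDITIONS = _glm.CONDITIONS  # (target, context) pairs, 4 of them


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic participant/cohort.

    Amplitudes are per-voxel signal SDs in beta units; ``noise_sd`` is the
    beta-noise SD.  Guidance probabilities are the chance that an
    anchor-directed first fixation lands on the associated anchor;
    ``dprime_mean``/``dprime_slope`` link a participant's guidance Δ% to
    their search d′.
    """

    anchor_amp: float = 0.5
    target_amp: float = 0.0
    context_amp: float = 0.5
    noise_sd: float = 1.0
    guidance_prob_present: float = 0.66
    guidance_prob_absent: float = 0.62
    guidance_prob_sd: float = 0.08       # between-participant spread
    anchor_directed_prob: float = 0.805  # first fixation goes to *an* anchor
    fixation_recorded_prob: float = 0.9415
    center_fixation_prob: float = 0.8333
    first_fix_latency_mean: float = 229.53  # ms
    first_fix_latency_sd: float = 29.20
    dprime_mean: float = 1.19
    dprime_slope: float = 0.012   # d′ per Δ% percentage point
    dprime_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if min(self.anchor_amp, self.target_amp, self.context_amp) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for p in (self.guidance_prob_present, self.guidance_prob_absent,
                  self.anchor_directed_prob, self.fixation_recorded_prob,
                  self.center_fixation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class BetaPatterns:
    """Run × condition × voxel beta array for one ROI/hemisphere."""

    values: np.ndarray                 # (n_runs, 4, n_voxels)
    condition_labels: list             # [(target, context), ...]
    hemisphere: str
    roi_name: str
    voxel_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.values.ndim != 3 or self.values.shape[1] != len(self.condition_labels):
            raise ValueError("values must be (n_runs, n_conditions, n_voxels)")
        if set(self.condition_labels) != set(CONDITIONS):
            raise ValueError("condition_labels must cover all 4 (target, context) pairs")
        if self.values.shape[2] != self.voxel_ids.size:
            raise ValueError("voxel axis must match voxel_ids")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    def subset(self, voxel_ids) -> "BetaPatterns":
        """Restrict to the given voxel ids (e.g., a sub-ROI)."""
        pos = {v: i for i, v in enumerate(self.voxel_ids.tolist())}
        idx = np.array([pos[v] for v in np.asarray(voxel_ids).tolist()], dtype=int)
        return BetaPatterns(values=self.values[:, :, idx],
                            condition_labels=list(self.condition_labels),
                            hemisphere=self.hemisphere, roi_name=self.roi_name,
                            voxel_ids=np.asarray(voxel_ids))


def _unit_rms_patterns(rng, n_patterns: int, n_voxels: int) -> np.ndarray:
    """Random direction vectors scaled to Euclidean norm √n_voxels."""
    P = rng.standard_normal((n_patterns, n_voxels))
    P *= np.sqrt(n_voxels) / np.linalg.norm(P, axis=1, keepdims=True)
    return P


def simulate_participant_betas(gt: GroundTruth, association=None, n_runs: int = 8,
                               n_voxels_per_hemisphere: int = 264,
                               roi_names=("LOC",), baseline: float = 0.0,
                               seed=None):
    """Simulate run-wise condition betas per ROI and hemisphere.

    beta(run, cond, v) = baseline + anchor_amp·P_anchor[assoc(cond)][v]
    + target_amp·P_target[cond.target][v] + context_amp·P_context[cond.context][v]
    + N(0, noise_sd).  The anchor pattern is keyed by the *associated* anchor
    under the association map, hence identical for the same anchor across
    contexts.  Hemispheres get independent patterns and noise.

    Returns ``({(roi_name, hemisphere): BetaPatterns}, gt)``.
    """
    if n_voxels_per_hemisphere <= 0:
        raise ValueError("need at least one voxel per hemisphere")
    if n_runs < 2:
        raise ValueError("cross-validation needs >= 2 runs")
    association = association or _design.make_association_map(0)
    rng = as_rng(seed if seed is not None else gt.seed)
    out = {}
    for roi in roi_names:
        for hemi in ("left", "right"):
            nv = n_voxels_per_hemisphere
            P_anchor = {a: p for a, p in zip(_design.ANCHORS, _unit_rms_patterns(rng, 2, nv))}
            P_target = {t: p for t, p in zip(_design.TARGETS, _unit_rms_patterns(rng, 2, nv))}
            P_context = {c: p for c, p in zip(_design.CONTEXTS, _unit_rms_patterns(rng, 2, nv))}
            vals = np.empty((n_runs, len(CONDITIONS), nv))
            for ci, (target, context) in enumerate(CONDITIONS):
                anchor = association.anchor_for(target, context)
                mean = (baseline
                        + gt.anchor_amp * P_anchor[anchor]
                        + gt.target_amp * P_target[target]
                        + gt.context_amp * P_context[context])
                vals[:, ci, :] = mean
            vals += rng.standard_normal(vals.shape) * gt.noise_sd
            out[(roi, hemi)] = BetaPatterns(values=vals, condition_labels=list(CONDITIONS),
                                            hemisphere=hemi, roi_name=roi,
                                            voxel_ids=np.arange(nv))
    return out, gt


@dataclass
class LocalizerTruth:
    """Ground-truth selectivity labels of simulated localizer voxels."""

    target_selective: np.ndarray  # boolean per voxel
    anchor_selective: np.ndarray


def simulate_localizer_betas(gt: GroundTruth, n_runs: int = 4, n_voxels: int = 600,
                             selective_fraction: float = 0.2, effect: float = 1.0,
                             seed=None):
    """Simulate localizer run betas over the 8 (stimulus × location) conditions.

    A seeded ``selective_fraction`` of voxels carries a book-vs-bowl mean
    difference of ±``effect``; an independent (possibly overlapping) subset
    carries a table_1-vs-table_2 difference.  Returns
    ``(betas (n_runs, 8, n_voxels), LocalizerTruth)``.
    """
    if not 0.0 <= selective_fraction <= 1.0:
        raise ValueError("selective_fraction must lie in [0, 1]")
    rng = as_rng(seed if seed is not None else gt.seed)
    n_sel = int(round(selective_fraction * n_voxels))
    tgt_sel = np.zeros(n_voxels, bool)
    anc_sel = np.zeros(n_voxels, bool)
    tgt_sel[rng.choice(n_voxels, n_sel, replace=False)] = True
    anc_sel[rng.choice(n_voxels, n_sel, replace=False)] = True
    tgt_sign = rng.choice([-1.0, 1.0], size=n_voxels)
    anc_sign = rng.choice([-1.0, 1.0], size=n_voxels)

    mean = np.zeros((len(_glm.LOCALIZER_CONDITIONS), n_voxels))
    for i, name in enumerate(_glm.LOCALIZER_CONDITIONS):
        stim = name.rsplit("_", 1)[0]
        if stim == "book":
            mean[i] += tgt_sel * tgt_sign * effect / 2
        elif stim == "bowl":
            mean[i] -= tgt_sel * tgt_sign * effect / 2
        elif stim == "table_1":
            mean[i] += anc_sel * anc_sign * effect / 2
        elif stim == "table_2":
            mean[i] -= anc_sel * anc_sign * effect / 2
    betas = mean[None] + rng.standard_normal((n_runs, mean.shape[0], n_voxels)) * gt.noise_sd
    return betas, LocalizerTruth(target_selective=tgt_sel, anchor_selective=anc_sel)


def participant_guidance_probs(gt: GroundTruth, rng) -> tuple:
    """Draw one participant's (present, absent) guidance probabilities,
    jittered around the population values and clipped to [0, 1]."""
    shift = rng.normal(0.0, gt.guidance_prob_sd)
    return (float(np.clip(gt.guidance_prob_present + shift, 0.0, 1.0)),
            float(np.clip(gt.guidance_prob_absent + shift, 0.0, 1.0)))


def simulate_fixations(trials, gt: GroundTruth, aois: _gaze.AoiSet | None = None,
                       guidance_probs: tuple | None = None, seed=None) -> list:
    """Simulate fixation sequences for the search trials.

    Each search trial gets (with dropout) an onset fixation inside the center
    AOI, then with probability ``anchor_directed_prob`` an anchor-directed
    first fixation landing on the associated anchor with the guidance
    probability for that trial's presence condition (else on the other
    anchor); non-anchor-directed fixations land outside all AOIs.  First-
    fixation latency is Normal(229.53 ms, 29.20 ms) truncated at 0.
    """
    aois = aois or _gaze.AoiSet()
    rng = as_rng(seed if seed is not None else gt.seed)
    gp, ga = guidance_probs or (gt.guidance_prob_present, gt.guidance_prob_absent)
    records = []
    for t in trials:
        if t.trial_type != "search":
            continue
        ref = t.run * 1000 + t.trial_index
        if rng.random() >= gt.fixation_recorded_prob:
            continue  # no fixation recorded during the scene
        ordinal = 0
        in_center = rng.random() < gt.center_fixation_prob
        if in_center:
            x = rng.uniform(-aois.center_rect.width / 2, aois.center_rect.width / 2) * 0.5
            y = rng.uniform(-aois.center_rect.height / 2, aois.center_rect.height / 2) * 0.5
        else:  # onset gaze drifted out of the center AOI → trial excluded later
            x, y = aois.center_rect.width, aois.center_rect.height
        latency = max(rng.normal(gt.first_fix_latency_mean, gt.first_fix_latency_sd), 1.0)
        records.append(_gaze.FixationRecord(trial_ref=ref, x=x, y=y,
                                            onset=-50.0, duration=50.0 + latency - 1.0,
                                            ordinal=ordinal))
        ordinal += 1
        if rng.random() < gt.anchor_directed_prob:
            p = gp if t.target_present else ga
            to_assoc = rng.random() < p
            side = t.anchor_side if to_assoc else ("left" if t.anchor_side == "right" else "right")
            rect = aois.rect(side)
            x = rng.uniform(rect.cx - rect.width / 2, rect.cx + rect.width / 2)
            y = rng.uniform(rect.cy - rect.height / 2, rect.cy + rect.height / 2)
        else:  # elsewhere in the scene, outside every AOI
            x = 0.0
            y = aois.center_rect.height  # above all rectangles
        records.append(_gaze.FixationRecord(trial_ref=ref, x=x, y=y, onset=latency,
                                            duration=200.0, ordinal=ordinal))
    return records


def simulate_responses(trials, gt: GroundTruth, participant_guidance: float,
                       seed=None) -> pd.DataFrame:
    """Simulate present/absent responses from an equal-variance SDT model.

    The participant's d′ is ``dprime_mean + dprime_slope·(Δ% − E[Δ%]) +
    N(0, dprime_noise_sd)`` where Δ% is ``participant_guidance`` and E[Δ%]
    the population expectation implied by the generator; the criterion sits
    at d′/2 (unbiased).  Returns a frame (run, trial_index, reported_present,
    correct) over search trials, plus the latent d′ as ``frame.attrs["dprime"]``.
    """
    rng = as_rng(seed if seed is not None else gt.seed)
    expected_delta = 100.0 * gt.anchor_directed_prob * (2 * gt.guidance_prob_absent - 1)
    dp = gt.dprime_mean + gt.dprime_slope * (participant_guidance - expected_delta)
    dp += rng.normal(0.0, gt.dprime_noise_sd)
    hit_p = norm.cdf(dp / 2)
    fa_p = norm.cdf(-dp / 2)
    rows = []
    for t in trials:
        if t.trial_type != "search":
            continue
        p_yes = hit_p if t.target_present else fa_p
        said_yes = bool(rng.random() < p_yes)
        rows.append((t.run, t.trial_index, said_yes, said_yes == t.target_present))
    df = pd.DataFrame(rows, columns=["run", "trial_index", "reported_present", "correct"])
    df.attrs["dprime"] = float(dp)
    return df


def simulate_timeseries(betas: BetaPatterns, trials, tr: float = 1.5,
                        n_scans: int = 198, noise_sd: float = 0.0,
                        ar_coef: float = 0.0, seed=None):
    """Generate per-run voxel time series Y = X·B + ε from beta patterns.

    ``trials`` must cover the runs in ``betas``; ε is white Gaussian noise,
    optionally AR(1) with coefficient ``ar_coef``.  Returns
    ``{run: (Y (n_scans, n_voxels), DesignMatrix)}``.
    """
    rng = as_rng(seed)
    duration = n_scans * tr
    last = max(t.preview_offset for t in trials)
    if last > duration:
        raise ValueError(f"n_scans·tr = {duration} s does not cover the last "
                         f"trial offset at {last} s")
    out = {}
    for run in range(betas.n_runs):
        run_trials = [t for t in trials if t.run == run]
        X = _glm.build_design_matrix(run_trials, tr=tr, n_scans=n_scans)
        B = np.zeros((X.values.shape[1], betas.values.shape[2]))
        for ci, (target, context) in enumerate(CONDITIONS):
            j = X.column_names.index(_glm.condition_name(target, context))
            B[j] = betas.values[run, ci]
        Y = X.values @ B
        if noise_sd > 0:
            eps = rng.standard_normal(Y.shape) * noise_sd
            if ar_coef:
                for i in range(1, eps.shape[0]):
                    eps[i] += ar_coef * eps[i - 1]
            Y = Y + eps
        out[run] = (Y, X)
    return out


def betas_to_frame(patterns: dict) -> pd.DataFrame:
    """Compact tabular export: (roi, hemisphere, run, target, context,
    voxel_id, value) long format."""
    rows = []
    for (roi, hemi), bp in patterns.items():
        for r in range(bp.n_runs):
            for ci, (target, context) in enumerate(bp.condition_labels):
                for v, val in zip(bp.voxel_ids, bp.values[r, ci]):
                    rows.append((roi, hemi, r, target, context, int(v), float(val)))
    return pd.DataFrame(rows, columns=["roi", "hemisphere", "run", "target",
                                       "context", "voxel_id", "value"])


def frame_to_betas(df: pd.DataFrame) -> dict:
    """Inverse of :func:`betas_to_frame`."""
    out = {}
    for (roi, hemi), sub in df.groupby(["roi", "hemisphere"]):
        runs = sorted(sub["run"].unique())
        vox = np.array(sorted(sub["voxel_id"].unique()))
        vals = np.empty((len(runs), len(CONDITIONS), vox.size))
        piv = {(r.run, r.target, r.context, r.voxel_id): r.value for r in sub.itertuples()}
        vpos = {v: i for i, v in enumerate(vox.tolist())}
        for r in runs:
            for ci, (t, c) in enumerate(CONDITIONS):
                for v in vox:
                    vals[r, ci, vpos[int(v)]] = piv[(r, t, c, int(v))]
        out[(roi, hemi)] = BetaPatterns(values=vals, condition_labels=list(CONDITIONS),
                                        hemisphere=hemi, roi_name=roi, voxel_ids=vox)
    return out
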