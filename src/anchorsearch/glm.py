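"""Run-wise GLM beta estimation and localizer F-contrasts.

Condition regressors are boxcars spanning the scene preview, convolved with
the canonical double-gamma hemodynamic response function and sampled at scan
acquisition times.  The search-task model contains the four (target × scene
context) regressors of interest built from preview-only trials, six motion
nuisance regressors and a constant; betas are estimated per run by ordinary
least squares.  Localizer selectivity is a one-way F statistic across
condition groups with run betas as replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from anchorsearch import design as _design

OVERSAMPLING = 16  # regressors built on a tr/16 grid before downsampling


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds).

    Defaults are the widely used canonical settings: response peak at 6 s,
    undershoot at 16 s, unit dispersions, peak:undershoot ratio 6, 32-s
    kernel.
    """

    tr: float = 1.5
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self):
        vals = (self.tr, self.peak_delay, self.undershoot_delay, self.peak_dispersion,
                self.undershoot_dispersion, self.peak_undershoot_ratio, self.kernel_length)
        if any(v <= 0 for v in vals):
            raise ValueError("all HRF parameters must be positive")
        if self.kernel_length < self.peak_delay:
            raise ValueError("kernel_length must cover the response peak")


@dataclass
class DesignMatrix:
    """Design matrix with disjoint interest/nuisance column index sets."""

    values: np.ndarray  # (n_scans, n_regressors)
    column_names: list
    interest_columns: list
    nuisance_columns: list
    empty_interest: list = None  # names of all-zero interest columns

    def __post_init__(self):
        ic, nc = set(self.interest_columns), set(self.nuisance_columns)
        if ic & nc or ic | nc != set(range(self.values.shape[1])):
            raise ValueError("interest/nuisance columns must partition all columns")
        if self.empty_interest is None:
            self.empty_interest = []


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp / scale
                      - gammaln(shape) - shape * np.log(scale))
    return out


def canonical_hrf(params: HrfParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at resolution tr/16.

    The kernel is the difference of two gamma densities (undershoot scaled by
    1/ratio), truncated at ``kernel_length`` and normalized to unit peak.
    """
    params = params or HrfParams()
    dt = params.tr / OVERSAMPLING
    t = np.arange(0, params.kernel_length + dt / 2, dt)
    peak = _gamma_pdf(t, params.peak_delay / params.peak_dispersion, params.peak_dispersion)
    under = _gamma_pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                       params.undershoot_dispersion)
    h = peak - under / params.peak_undershoot_ratio
    return h / np.max(np.abs(h))


CONDITIONS = tuple((t, c) for t in _design.TARGETS for c in _design.CONTEXTS)


def condition_name(target: str, context: str) -> str:
    return f"{target}_{context}"


def build_design_matrix(trials, tr: float = 1.5, n_scans: int = 198,
                        hrf: HrfParams | np.ndarray | None = None,
                        motion: np.ndarray | None = None) -> DesignMatrix:
    """Build one run's design matrix from its trials.

    Interest columns are the four (target × context) conditions, built from
    preview-only trials only as boxcars from preview onset to offset,
    convolved with the HRF and sampled at scan times k·tr.  Nuisance columns
    are six motion regressors (zeros if ``motion`` is None) and a constant.
    Overlapping boxcars within a condition sum.  Conditions with no trials in
    the run yield all-zero columns, recorded in ``empty_interest``.
    """
    if n_scans <= 0:
        raise ValueError("n_scans must be positive")
    if isinstance(hrf, np.ndarray):
        kernel = hrf
        dt = tr / OVERSAMPLING
    else:
        hp = hrf or HrfParams(tr=tr)
        if hp.tr != tr:
            hp = HrfParams(tr, hp.peak_delay, hp.undershoot_delay, hp.peak_dispersion,
                           hp.undershoot_dispersion, hp.peak_undershoot_ratio, hp.kernel_length)
        kernel = canonical_hrf(hp)
        dt = tr / OVERSAMPLING
    duration = n_scans * tr
    n_fine = int(np.ceil(duration / dt)) + kernel.size
    scan_idx = (np.arange(n_scans) * tr / dt).round().astype(int)

    cols, names, empty = [], [], []
    for target, context in CONDITIONS:
        box = np.zeros(n_fine)
        for t in trials:
            if not (t.is_preview_only and t.target == target and t.context == context):
                continue
            if t.preview_onset >= duration:
                raise ValueError(f"trial onset {t.preview_onset} outside scan window")
            i0 = int(round(t.preview_onset / dt))
            i1 = int(round(t.preview_offset / dt))
            box[i0:i1] += 1.0
        # dt factor approximates the continuous-time convolution integral,
        # so a sustained boxcar plateaus at the kernel integral
        reg = np.convolve(box, kernel)[:n_fine][scan_idx] * dt
        if not np.any(reg):
            empty.append(condition_name(target, context))
        cols.append(reg)
        names.append(condition_name(target, context))

    if motion is None:
        motion = np.zeros((n_scans, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_scans, 6):
        raise ValueError("motion must be an (n_scans, 6) array")
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j}")
    cols.append(np.ones(n_scans))
    names.append("constant")

    X = np.column_stack(cols)
    n_int = len(CONDITIONS)
    return DesignMatrix(values=X, column_names=names,
                        interest_columns=list(range(n_int)),
                        nuisance_columns=list(range(n_int, X.shape[1])),
                        empty_interest=empty)


def fit_ols(Y: np.ndarray, X: DesignMatrix):
    """Ordinary least squares fit of time × voxel data.

    Returns ``(betas, residuals, df)`` with ``df = n_scans − rank(X)``.
    Rank-deficient *interest* columns raise (naming the confounded
    conditions); redundant nuisance columns are dropped with a warning and
    their betas reported as 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.values.shape[0]:
        raise ValueError("Y rows must match the number of scans")
    Xv = X.values
    interest = [i for i in X.interest_columns
                if X.column_names[i] not in (X.empty_interest or [])]
    if interest:
        sub = Xv[:, interest]
        if np.linalg.matrix_rank(sub) < len(interest):
            raise ValueError("rank-deficient interest columns: "
                             + ", ".join(X.column_names[i] for i in interest))
    keep = list(range(Xv.shape[1]))
    rank_full = np.linalg.matrix_rank(Xv)
    if rank_full < Xv.shape[1]:
        # greedily drop redundant nuisance columns (empty interest columns
        # also contribute nothing and are left in place: lstsq handles them)
        for j in reversed(X.nuisance_columns):
            trial = [k for k in keep if k != j]
            if np.linalg.matrix_rank(Xv[:, trial]) == rank_full:
                keep = trial
                warnings.warn(f"dropping rank-deficient nuisance column {X.column_names[j]!r}")
            if len(keep) == rank_full:
                break
    beta_kept, *_ = np.linalg.lstsq(Xv[:, keep], Y, rcond=None)
    betas = np.zeros((Xv.shape[1], Y.shape[1]))
    betas[keep] = beta_kept
    residuals = Y - Xv @ betas
    df = Y.shape[0] - rank_full
    return betas, residuals, df


def f_contrast(run_betas: np.ndarray, groups):
    """One-way F across condition groups, run betas as replicates.

    ``run_betas`` is (n_runs, n_conditions) or (n_runs, n_conditions,
    n_voxels); ``groups`` is a sequence of condition-index groups (≥ 2).
    Betas are averaged within each (run × group) cell first, so each group
    contributes one replicate per run and df = (k − 1, k·(n_runs − 1)).
    Zero within-group variance with distinct means gives F = +inf, p = 0.
    """
    rb = np.asarray(run_betas, dtype=float)
    squeeze = rb.ndim == 2
    if squeeze:
        rb = rb[:, :, None]
    n_runs = rb.shape[0]
    if n_runs < 2:
        raise ValueError("need >= 2 runs")
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("contrast must partition >= 2 groups")
    k = len(groups)
    cell = np.stack([rb[:, g, :].mean(axis=1) for g in groups])  # (k, n_runs, V)
    grand = cell.mean(axis=(0, 1))
    gmean = cell.mean(axis=1)  # (k, V)
    ss_between = n_runs * ((gmean - grand) ** 2).sum(axis=0)
    ss_within = ((cell - gmean[:, None, :]) ** 2).sum(axis=(0, 1))
    df1, df2 = k - 1, k * (n_runs - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    F = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), F)
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isfinite(F), F, 0.0), df1, df2))
    p = np.where((F == 0) & (ss_within == 0), 1.0, p)
    if squeeze:
        return float(F[0]), float(p[0])
    return F, p


LOCALIZER_CONDITIONS = tuple(f"{stim}_{loc}" for stim in
                             ("book", "bowl", "table_1", "table_2")
                             for loc in ("central", "peripheral"))


def localizer_contrasts(loc_betas: np.ndarray):
    """Target and anchor localizer F-contrasts.

    ``loc_betas`` is (n_runs, 8, n_voxels) over ``LOCALIZER_CONDITIONS``.
    The target contrast groups book vs. bowl conditions (central+peripheral
    pooled), the anchor contrast table_1 vs. table_2.  Returns
    ``(F_target, p_target, F_anchor, p_anchor)`` per voxel.
    """
    if loc_betas.ndim != 3 or loc_betas.shape[1] != len(LOCALIZER_CONDITIONS):
        raise ValueError("expected (n_runs, 8, n_voxels) localizer betas")
    idx = {name: i for i, name in enumerate(LOCALIZER_CONDITIONS)}
    tgt_groups = [[idx["book_central"], idx["book_peripheral"]],
                  [idx["bowl_central"], idx["bowl_peripheral"]]]
    anc_groups = [[idx["table_1_central"], idx["table_1_peripheral"]],
                  [idx["table_2_central"], idx["table_2_peripheral"]]]
    Ft, pt = f_contrast(loc_betas, tgt_groups)
    Fa, pa = f_contrast(loc_betas, anc_groups)
    return Ft, pt, Fa, pa
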