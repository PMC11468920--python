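"""Group-level inference.

Three nonparametric tools carry all group statistics:

- participant bootstrap tests against chance (percentile CI, two-tailed p),
- threshold-free cluster enhancement (TFCE) over 1-D sub-ROI curves or 3-D
  maps: TFCE(p) = Σ_h e(h, p)**E · h**H · dh over the threshold ladder
  h = dh, 2dh, … with e(h, p) the extent of the supra-threshold connected
  component containing p,
- sign-flip permutation nulls of the maximum TFCE score for family-wise
  error control (max-statistic correction).

Permutation and bootstrap p-values use the +1 finite-sample correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from anchorsearch._rng import as_rng


@dataclass
class GroupStat:
    """Bootstrap summary of a per-participant statistic."""

    observed_mean: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    n_boot: int
    seed: object = None


@dataclass(frozen=True)
class TfceParams:
    """TFCE parameters: extent exponent E, height exponent H, threshold step
    dh (``None`` → max statistic / 100), permutation count, tail."""

    extent_exponent: float = 0.5
    height_exponent: float = 2.0
    dh: float | None = None
    n_permutations: int = 10000
    seed: object = None
    tail: str = "two_sided"  # or "one_sided_positive"

    def __post_init__(self):
        if self.extent_exponent < 0 or self.height_exponent < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.tail not in ("two_sided", "one_sided_positive"):
            raise ValueError(f"unknown tail {self.tail!r}")


def bootstrap_test(values, n_boot: int = 10000, seed=None, null_value: float = 0.0) -> GroupStat:
    """Bootstrap test of the participant mean against ``null_value``.

    Participants are resampled with replacement ``n_boot`` times; the CI is
    the 2.5/97.5 percentile interval of the resampled means and
    p = 2·min(#{mean* ≤ null}+1, #{mean* ≥ null}+1)/(n_boot+1), capped at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need >= 2 participant values")
    if np.unique(values).size < 2:
        warnings.warn("fewer than 2 distinct values; bootstrap CI is degenerate")
    rng = as_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    p = 2.0 * min(np.sum(means <= null_value) + 1, np.sum(means >= null_value) + 1) / (n_boot + 1)
    return GroupStat(observed_mean=float(values.mean()), ci_low=float(lo), ci_high=float(hi),
                     p_two_tailed=float(min(p, 1.0)), n_boot=n_boot, seed=seed)


def _tfce_positive(stat_map: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    """Enhance the positive part of an n-D grid map (orthogonal adjacency)."""
    out = np.zeros_like(stat_map, dtype=float)
    top = float(stat_map.max(initial=0.0))
    if top <= 0:
        return out
    structure = ndimage.generate_binary_structure(stat_map.ndim, 1)
    h = dh
    while h <= top + 1e-12:
        supra = stat_map >= h
        if not supra.any():
            break
        lab, n_lab = ndimage.label(supra, structure=structure)
        sizes = np.bincount(lab.ravel())
        extent = sizes[lab]
        out[supra] += extent[supra] ** E * h ** H * dh
        h += dh
    return out


def tfce(stat_map, params: TfceParams) -> np.ndarray:
    """TFCE-enhance a 1-D curve or n-D grid map.

    Adjacency is the chain for 1-D input and face-connectivity for grids.
    Under the two-sided tail the negative part is enhanced separately and
    subtracted, so the output keeps the sign of the input.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.size == 0:
        raise ValueError("empty map")
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("map must be finite")
    scale = float(np.max(np.abs(stat_map), initial=0.0))
    if scale == 0.0:
        return np.zeros_like(stat_map)
    dh = params.dh if params.dh is not None else scale / 100.0
    pos = _tfce_positive(stat_map, params.extent_exponent, params.height_exponent, dh)
    if params.tail == "one_sided_positive":
        return pos
    neg = _tfce_positive(-stat_map, params.extent_exponent, params.height_exponent, dh)
    return pos - neg


def _tfce_1d_batch(maps: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    """Vectorized positive-part TFCE over a batch of 1-D maps (B, L)."""
    B, L = maps.shape
    out = np.zeros_like(maps, dtype=float)
    top = float(maps.max(initial=0.0))
    if top <= 0:
        return out
    h = dh
    while h <= top + 1e-12:
        supra = maps >= h
        if not supra.any():
            break
        # pad a False column so runs never cross row boundaries
        padded = np.concatenate([np.zeros((B, 1), bool), supra], axis=1)
        starts = padded[:, 1:] & ~padded[:, :-1]
        run_id = np.cumsum(starts.ravel()) * supra.ravel()
        sizes = np.bincount(run_id)
        sizes[0] = 0
        extent = sizes[run_id].reshape(B, L)
        out[supra] += extent[supra] ** E * h ** H * dh
        h += dh
    return out


def one_sample_t(group_data: np.ndarray) -> np.ndarray:
    """One-sample t map across the participant axis (axis 0)."""
    n = group_data.shape[0]
    m = group_data.mean(axis=0)
    sd = group_data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def signflip_null(group_data: np.ndarray, params: TfceParams):
    """Sign-flip permutation null of the maximum TFCE score.

    ``group_data`` is participant × positions (1-D curve) or participant ×
    grid.  Each permutation flips every participant's map by an independent
    ±1, recomputes the one-sample t map, TFCE-enhances it, and records the
    spatial maximum (of |TFCE| under the two-sided tail).

    Returns ``(observed_tfce, null_max)``.
    """
    group_data = np.asarray(group_data, dtype=float)
    if group_data.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    rng = as_rng(params.seed)
    n_sub = group_data.shape[0]
    t_obs = one_sample_t(group_data)
    scale = float(np.max(np.abs(t_obs), initial=0.0))
    dh = params.dh if params.dh is not None else (scale / 100.0 if scale > 0 else 0.01)
    obs = tfce(t_obs, TfceParams(params.extent_exponent, params.height_exponent, dh,
                                 params.n_permutations, params.seed, params.tail))

    if group_data.ndim == 2:  # 1-D maps: fully vectorized permutation loop
        flips = rng.choice([-1.0, 1.0], size=(params.n_permutations, n_sub))
        flipped = flips[:, :, None] * group_data[None, :, :]  # (P, S, L)
        m = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(sd > 0, m / (sd / np.sqrt(n_sub)), 0.0)
        E, H = params.extent_exponent, params.height_exponent
        pos = _tfce_1d_batch(t_perm, E, H, dh)
        if params.tail == "two_sided":
            neg = _tfce_1d_batch(-t_perm, E, H, dh)
            null_max = np.maximum(pos, neg).max(axis=1)
        else:
            null_max = pos.max(axis=1)
        return obs, null_max

    null_max = np.empty(params.n_permutations)
    sub_params = TfceParams(params.extent_exponent, params.height_exponent, dh,
                            params.n_permutations, None, params.tail)
    for i in range(params.n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n_sub).reshape((n_sub,) + (1,) * (group_data.ndim - 1))
        t_perm = one_sample_t(group_data * flips)
        enh = tfce(t_perm, sub_params)
        null_max[i] = np.max(np.abs(enh)) if params.tail == "two_sided" else np.max(enh)
    return obs, null_max


def maxstat_correct(observed_tfce: np.ndarray, null_max: np.ndarray):
    """Corrected p map and z map from the max-statistic null.

    p(pos) = (#{null_max ≥ observed(pos)} + 1) / (n_perm + 1);
    z = Φ⁻¹(1 − p).  For two-sided observed maps pass |observed| (handled
    here), the sign being reattached to z.
    """
    null_max = np.asarray(null_max, dtype=float)
    if null_max.size == 0:
        raise ValueError("null distribution is empty")
    obs = np.asarray(observed_tfce, dtype=float)
    mag = np.abs(obs)
    n_perm = null_max.size
    counts = np.sum(null_max[None, :] >= mag.reshape(-1, 1), axis=1).reshape(obs.shape)
    p = (counts + 1.0) / (n_perm + 1.0)
    # z transform clipped one permutation step away from p=1 to stay finite
    z = sps.norm.isf(np.minimum(p, n_perm / (n_perm + 1.0)))
    z = z * np.where(obs < 0, -1.0, 1.0)
    return p, z


def tfce_curve_test(group_curves: np.ndarray, params: TfceParams | None = None):
    """Sign-flip TFCE test over participant × ROI-size curves.

    Returns ``(corrected_p, z, observed_tfce)`` with positions along the
    sub-ROI size axis (chain adjacency).
    """
    params = params or TfceParams()
    obs, null_max = signflip_null(group_curves, params)
    p, z = maxstat_correct(obs, null_max)
    return p, z, obs


def pearson_correlation(x, y):
    """Sample Pearson r with a two-sided p from the t transform (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired inputs of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
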