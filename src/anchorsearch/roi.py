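"""Localizer-driven ROI construction.

Participant ROIs intersect an anatomical group mask with voxels that
discriminate targets (book vs. bowl) or anchors (table_1 vs. table_2) in the
independent localizer (p < α, uncorrected), taking the union of the two
selective sets.  Graded "sub-ROIs" of increasing size then take an equal
number of the top-most target- and anchor-selective voxels, nested up to a
per-hemisphere maximum (e.g., 424 voxels for EVC, 264 for LOC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RoiMask:
    """Ordered voxel index set with per-voxel localizer selectivity."""

    roi_name: str
    hemisphere: str
    voxel_ids: np.ndarray
    f_target: np.ndarray
    p_target: np.ndarray
    f_anchor: np.ndarray
    p_anchor: np.ndarray
    source_alpha: float = 0.05

    def __post_init__(self):
        self.voxel_ids = np.asarray(self.voxel_ids)
        if np.unique(self.voxel_ids).size != self.voxel_ids.size:
            raise ValueError("voxel_ids must be unique")
        for name in ("f_target", "p_target", "f_anchor", "p_anchor"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.voxel_ids.shape:
                raise ValueError(f"{name} must align with voxel_ids")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.voxel_ids.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel_id": self.voxel_ids,
                             "F_target": self.f_target, "p_target": self.p_target,
                             "F_anchor": self.f_anchor, "p_anchor": self.p_anchor})


def select_roi_voxels(group_mask, f_target, p_target, f_anchor, p_anchor,
                      alpha: float = 0.05, roi_name: str = "ROI",
                      hemisphere: str = "left") -> RoiMask:
    """Union of target- and anchor-selective voxels within a group mask.

    ``group_mask`` is a sequence of voxel ids; the F/p arrays are indexed by
    voxel id (i.e., cover at least ``max(group_mask)+1`` voxels).  A voxel is
    kept if its target *or* anchor contrast is significant at ``alpha``
    (uncorrected).  An empty result warns and returns an empty mask.
    """
    group_mask = np.asarray(sorted(group_mask))
    f_target = np.asarray(f_target, dtype=float)
    p_target = np.asarray(p_target, dtype=float)
    f_anchor = np.asarray(f_anchor, dtype=float)
    p_anchor = np.asarray(p_anchor, dtype=float)
    if group_mask.size and group_mask.max() >= p_target.size:
        raise ValueError("selectivity maps must cover the group mask")
    keep = (p_target[group_mask] < alpha) | (p_anchor[group_mask] < alpha)
    ids = group_mask[keep]
    if ids.size == 0:
        warnings.warn(f"no selective voxels at alpha={alpha} in {roi_name}/{hemisphere}")
    return RoiMask(roi_name=roi_name, hemisphere=hemisphere, voxel_ids=ids,
                   f_target=f_target[ids], p_target=p_target[ids],
                   f_anchor=f_anchor[ids], p_anchor=p_anchor[ids],
                   source_alpha=alpha)


def _interleaved_order(mask: RoiMask) -> np.ndarray:
    """Total voxel order alternating the target- and anchor-F rankings.

    Ties break by voxel id (ascending), so the order is deterministic.
    Already-taken voxels are skipped, which backfills overlap between the two
    top lists alternately; the target list leads, so odd sizes give the
    target ranking the extra voxel.
    """
    by_target = np.lexsort((mask.voxel_ids, -mask.f_target))
    by_anchor = np.lexsort((mask.voxel_ids, -mask.f_anchor))
    taken = np.zeros(len(mask), bool)
    order = []
    it, ia = 0, 0
    for k in range(len(mask)):
        src = by_target if k % 2 == 0 else by_anchor
        i = it if k % 2 == 0 else ia
        while i < len(mask) and taken[src[i]]:
            i += 1
        if k % 2 == 0:
            it = i
        else:
            ia = i
        if i >= len(mask):  # one ranking exhausted; fall through to the other
            src = by_anchor if k % 2 == 0 else by_target
            i = ia if k % 2 == 0 else it
            while taken[src[i]]:
                i += 1
        order.append(src[i])
        taken[src[i]] = True
    return np.array(order, dtype=int)


def sub_roi_sizes(max_voxels: int, n_steps: int = 5) -> list:
    """Equidistant sub-ROI sizes: round(k · max / n_steps), k = 1..n_steps."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return [int(round(k * max_voxels / n_steps)) for k in range(1, n_steps + 1)]


def make_sub_rois(mask: RoiMask, n_steps: int = 5,
                  max_voxels_per_hemisphere: int | None = None) -> list:
    """Nested sub-ROIs of graded size from one hemisphere's mask.

    Sub-ROI k (size round(k·max/n_steps)) takes the leading voxels of an
    interleaved target/anchor selectivity ranking, which makes the equal
    top-target/top-anchor split exact up to overlap backfill and guarantees
    nesting.  ``max_voxels_per_hemisphere`` is clipped to the mask size with
    a warning.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    max_vox = max_voxels_per_hemisphere if max_voxels_per_hemisphere is not None else len(mask)
    if max_vox > len(mask):
        warnings.warn(f"max_voxels {max_vox} exceeds mask size {len(mask)}; clipping")
        max_vox = len(mask)
    order = _interleaved_order(mask)
    subs = []
    for size in sub_roi_sizes(max_vox, n_steps):
        pick = np.sort(order[:size])
        subs.append(RoiMask(roi_name=f"{mask.roi_name}_sub{size}",
                            hemisphere=mask.hemisphere,
                            voxel_ids=mask.voxel_ids[pick],
                            f_target=mask.f_target[pick], p_target=mask.p_target[pick],
                            f_anchor=mask.f_anchor[pick], p_anchor=mask.p_anchor[pick],
                            source_alpha=mask.source_alpha))
    return subs
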