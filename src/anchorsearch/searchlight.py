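"""Sphere-based searchlight decoding maps and group-level correction.

A searchlight repeats a decoding analysis inside a small sphere centered on
every voxel of a feature mask, writing the classifier-information score at
the sphere's center.  The feature mask is derived from group-level tests on
localizer decoding maps; group inference on the resulting cross-scene maps
uses sign-flip TFCE with max-statistic correction, and significant clusters
are tabulated with peak coordinates in mm via the volume affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from anchorsearch import mvpa as _mvpa
from anchorsearch import stats as _stats
from anchorsearch import synth as _synth


@dataclass(frozen=True)
class SphereNeighborhood:
    """Integer voxel offsets forming a sphere around (0, 0, 0)."""

    radius: float
    offsets: np.ndarray  # (m, 3) int
    inclusion_rule: str = "euclidean_le"

    def __len__(self) -> int:
        return self.offsets.shape[0]


def sphere_offsets(radius: float, inclusion_rule: str = "euclidean_le") -> SphereNeighborhood:
    """All integer offsets with ‖o‖² ≤ r² (``euclidean_le``) or < r²
    (``euclidean_lt``).  Radius 5 with the ≤ rule yields 515 offsets.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if inclusion_rule not in ("euclidean_le", "euclidean_lt"):
        raise ValueError(f"unknown inclusion rule {inclusion_rule!r}")
    r = int(np.floor(radius))
    grid = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(grid, grid, grid, indexing="ij")
    sq = ox**2 + oy**2 + oz**2
    keep = sq <= radius**2 if inclusion_rule == "euclidean_le" else sq < radius**2
    offsets = np.column_stack([ox[keep], oy[keep], oz[keep]]).astype(int)
    if not ((offsets == 0).all(axis=1)).any():
        offsets = np.vstack([offsets, [0, 0, 0]])
    return SphereNeighborhood(radius=radius, offsets=offsets, inclusion_rule=inclusion_rule)


def make_feature_mask(target_maps: np.ndarray, anchor_maps: np.ndarray,
                      cortex_mask: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Group-level feature mask from localizer decoding maps.

    For each of the two map stacks (participant × volume), a one-sample
    one-sided t-test against chance (0) is run per voxel; the mask is the
    union of voxels passing either test at ``alpha`` (uncorrected),
    intersected with ``cortex_mask``.
    """
    cortex_mask = np.asarray(cortex_mask, bool)

    def _sig(maps):
        maps = np.asarray(maps, dtype=float)
        t = _stats.one_sample_t(maps)
        p = sps.t.sf(t, df=maps.shape[0] - 1)
        return p < alpha

    mask = (_sig(target_maps) | _sig(anchor_maps)) & cortex_mask
    if not mask.any():
        raise ValueError("feature mask is empty")
    return mask


def run_searchlight(volume_betas: np.ndarray, condition_labels, mask: np.ndarray,
                    neighborhood: SphereNeighborhood, association,
                    scheme: str = "anchor_cross_scene", C: float = 1.0) -> np.ndarray:
    """Per-participant searchlight information map.

    ``volume_betas`` is (n_runs, n_conditions, X, Y, Z); for each in-mask
    center the in-mask voxels within the sphere (clipped at volume borders)
    are decoded with :func:`anchorsearch.mvpa.run_scheme` and the score is
    written at the center.  Centers whose sphere holds < 2 usable voxels get
    NaN.
    """
    mask = np.asarray(mask, bool)
    shape = mask.shape
    vb = np.asarray(volume_betas, dtype=float)
    if vb.shape[2:] != shape:
        raise ValueError("volume betas and mask shapes differ")
    flat = vb.reshape(vb.shape[0], vb.shape[1], -1)
    out = np.full(shape, np.nan)
    centers = np.argwhere(mask)
    lin_mask = mask.ravel()
    for cx, cy, cz in centers:
        pts = neighborhood.offsets + (cx, cy, cz)
        ok = ((pts >= 0) & (pts < shape)).all(axis=1)
        pts = pts[ok]
        lin = np.ravel_multi_index(pts.T, shape)
        lin = lin[lin_mask[lin]]
        if lin.size < 2:
            warnings.warn(f"sphere at {(cx, cy, cz)} has < 2 usable voxels; skipped")
            continue
        betas = _synth.BetaPatterns(values=flat[:, :, lin],
                                    condition_labels=list(condition_labels),
                                    hemisphere="volume", roi_name="searchlight",
                                    voxel_ids=lin)
        res = _mvpa.run_scheme(betas, scheme, association, C=C)
        out[cx, cy, cz] = res.info
    return out


def group_searchlight(maps: np.ndarray, tfce_params: _stats.TfceParams | None = None,
                      affine: np.ndarray | None = None, cluster_alpha: float = 0.05):
    """Group TFCE inference on a stack of searchlight maps.

    ``maps`` is (n_participants, X, Y, Z); NaNs (out-of-mask) are treated as
    zeros.  Runs the sign-flip max-TFCE null, corrects with the max
    statistic, and tabulates suprathreshold clusters (corrected
    p < ``cluster_alpha``) with peak mm coordinates (via ``affine``), extent
    and volume.  Returns ``(p_map, z_map, cluster_table)``.
    """
    maps = np.nan_to_num(np.asarray(maps, dtype=float))
    if maps.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    params = tfce_params or _stats.TfceParams(tail="one_sided_positive", n_permutations=1000)
    affine = affine if affine is not None else np.diag([2.0, 2.0, 2.0, 1.0])
    obs, null_max = _stats.signflip_null(maps, params)
    p, z = _stats.maxstat_correct(obs, null_max)

    sig = p < cluster_alpha
    lab, n_lab = ndimage.label(sig, structure=ndimage.generate_binary_structure(3, 1))
    voxel_mm3 = float(abs(np.linalg.det(affine[:3, :3])))
    rows = []
    for k in range(1, n_lab + 1):
        vox = np.argwhere(lab == k)
        zvals = z[lab == k]
        peak = vox[np.argmax(zvals)]
        peak_mm = affine @ np.append(peak, 1.0)
        rows.append((k, peak_mm[0], peak_mm[1], peak_mm[2], len(vox),
                     len(vox) * voxel_mm3, float(zvals.max())))
    table = pd.DataFrame(rows, columns=["cluster_id", "peak_x_mm", "peak_y_mm",
                                        "peak_z_mm", "n_voxels", "volume_mm3", "peak_z"])
    return p, z, table


def save_map(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3-D map as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_map(path):
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine
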