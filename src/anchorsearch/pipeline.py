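"""End-to-end orchestration: configuration, the full synthetic pipeline and
its report bundle.

``run_pipeline`` executes: trial design → synthetic betas & localizer → ROI
selection & sub-ROIs → decoding (schemes × ROI sizes) → group bootstrap and
TFCE curve inference → gaze/behavioral analysis → (optional) small-volume
searchlight, writing result tables (TSV), a machine-readable JSON summary and
figures into the output directory.  All randomness derives from the config
seed; the same config yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import anchorsearch
from anchorsearch import design as _design
from anchorsearch import gaze as _gaze
from anchorsearch import glm as _glm
from anchorsearch import mvpa as _mvpa
from anchorsearch import roi as _roi
from anchorsearch import searchlight as _searchlight
from anchorsearch import stats as _stats
from anchorsearch import synth as _synth
from anchorsearch._rng import as_rng


class ConfigError(ValueError):
    """Aggregated configuration problems."""


@dataclass
class RoiSpec:
    n_voxels_per_hemisphere: int = 264
    max_subroi_voxels: int = 264


@dataclass
class SearchlightSpec:
    enabled: bool = False
    shape: tuple = (10, 10, 10)
    radius: float = 2.0
    n_permutations: int = 500
    blob_center: tuple = (5, 5, 5)
    blob_radius: float = 2.0


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 34
    n_runs: int = 8
    trials_per_run: int = 32
    rois: dict = field(default_factory=lambda: {"LOC": RoiSpec()})
    subroi_steps: int = 5
    roi_alpha: float = 0.05
    schemes: tuple = ("target_loro", "anchor_loro", "anchor_cross_scene")
    n_boot: int = 10000
    tfce: _stats.TfceParams = field(default_factory=lambda: _stats.TfceParams(n_permutations=1000))
    ground_truth: _synth.GroundTruth = field(default_factory=_synth.GroundTruth)
    localizer_selective_fraction: float = 0.5
    localizer_effect: float = 1.0
    searchlight: SearchlightSpec = field(default_factory=SearchlightSpec)
    output_dir: str = "anchorsearch_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output location is excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def _build(section: str, cls, raw: dict, errors: list):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(known)
    for k in sorted(unknown):
        errors.append(f"{section}: unknown key {k!r}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    for key in ("shape", "blob_center", "schemes"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        errors.append(f"{section}: {e}")
        return None


def validate_config(raw) -> PipelineConfig:
    """Parse and validate YAML text / dict into a PipelineConfig.

    Unknown keys are rejected; value errors are aggregated into one
    ConfigError.  An empty document yields the all-defaults config.
    """
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    raw = dict(raw)
    errors: list = []

    sub = {}
    if "rois" in raw:
        rois = raw.pop("rois")
        if not isinstance(rois, dict):
            errors.append("rois: must map ROI name to settings")
        else:
            sub["rois"] = {name: _build(f"rois.{name}", RoiSpec, spec or {}, errors)
                           for name, spec in rois.items()}
    if "tfce" in raw:
        sub["tfce"] = _build("tfce", _stats.TfceParams, raw.pop("tfce") or {}, errors)
    if "ground_truth" in raw:
        sub["ground_truth"] = _build("ground_truth", _synth.GroundTruth,
                                     raw.pop("ground_truth") or {}, errors)
    if "searchlight" in raw:
        sub["searchlight"] = _build("searchlight", SearchlightSpec,
                                    raw.pop("searchlight") or {}, errors)
    cfg = _build("config", PipelineConfig, raw, errors)
    if cfg is not None:
        for k, v in sub.items():
            if v is not None and not (isinstance(v, dict) and None in v.values()):
                setattr(cfg, k, v)
        if cfg.trials_per_run % _design.N_FACTOR_CELLS != 0:
            errors.append("trials_per_run: counterbalancing requires a multiple of 32")
        if cfg.n_participants < 2:
            errors.append("n_participants: need >= 2")
        if cfg.n_runs < 2:
            errors.append("n_runs: cross-validation needs >= 2 runs")
        if cfg.subroi_steps < 1:
            errors.append("subroi_steps: must be >= 1")
        if not 0 < cfg.roi_alpha <= 1:
            errors.append("roi_alpha: must lie in (0, 1]")
        for s in cfg.schemes:
            if s not in _mvpa.SCHEMES:
                errors.append(f"schemes: unknown scheme {s!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def load_config(path) -> PipelineConfig:
    return validate_config(Path(path).read_text())


def _simulate_and_decode(cfg: PipelineConfig, pid: int, seed_seq) -> tuple:
    """One participant: betas, localizer ROIs, decoding across schemes/sizes."""
    rng = as_rng(seed_seq)
    association = _design.make_association_map(pid % 4)
    gt = cfg.ground_truth
    results = []
    for roi_name, spec in cfg.rois.items():
        patterns, _ = _synth.simulate_participant_betas(
            gt, association, n_runs=cfg.n_runs,
            n_voxels_per_hemisphere=spec.n_voxels_per_hemisphere,
            roi_names=(roi_name,), seed=rng)
        # localizer-driven selectivity per hemisphere
        masks = {}
        for hemi in ("left", "right"):
            loc, _truth = _synth.simulate_localizer_betas(
                gt, n_voxels=spec.n_voxels_per_hemisphere,
                selective_fraction=cfg.localizer_selective_fraction,
                effect=cfg.localizer_effect, seed=rng)
            Ft, pt, Fa, pa = _glm.localizer_contrasts(loc)
            mask = _roi.select_roi_voxels(np.arange(spec.n_voxels_per_hemisphere),
                                          Ft, pt, Fa, pa, alpha=cfg.roi_alpha,
                                          roi_name=roi_name, hemisphere=hemi)
            if len(mask) == 0:  # fall back to the full group mask
                mask = _roi.RoiMask(roi_name, hemi,
                                    np.arange(spec.n_voxels_per_hemisphere),
                                    Ft, pt, Fa, pa, cfg.roi_alpha)
            masks[hemi] = mask
        sizes_masks = {"unrestricted": masks}
        max_vox = min(spec.max_subroi_voxels, min(len(m) for m in masks.values()))
        subs = {h: _roi.make_sub_rois(masks[h], n_steps=cfg.subroi_steps,
                                      max_voxels_per_hemisphere=max_vox)
                for h in masks}
        for k in range(cfg.subroi_steps):
            sizes_masks[f"sub{k + 1}"] = {h: subs[h][k] for h in subs}
        for size_name, hemi_masks in sizes_masks.items():
            hemi_betas = {h: patterns[(roi_name, h)].subset(m.voxel_ids)
                          for h, m in hemi_masks.items()}
            for scheme in cfg.schemes:
                res = _mvpa.run_scheme(hemi_betas, scheme, association,
                                       participant_id=pid)
                res.roi_name = f"{roi_name}:{size_name}"
                results.append(res)
    return association, results


def _behavior(cfg: PipelineConfig, pid: int, association, trials, seed_seq):
    rng = as_rng(seed_seq)
    gt = cfg.ground_truth
    probs = _synth.participant_guidance_probs(gt, rng)
    fixations = _synth.simulate_fixations(trials, gt, guidance_probs=probs, seed=rng)
    by_trial: dict = {}
    for f in fixations:
        by_trial.setdefault(f.trial_ref, []).append(f)
    aois = _gaze.AoiSet()
    labels = _gaze.first_fixation_labels(by_trial, aois)
    deltas = _gaze.guidance_delta(labels, trials, association)
    responses = _synth.simulate_responses(trials, gt,
                                          participant_guidance=deltas["absent"],
                                          seed=rng)
    summary = _gaze.behavioral_summary(pid, trials, by_trial, responses, aois, association)
    return summary, fixations, responses


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run the full synthetic pipeline; returns the summary dictionary."""
    cfg = config
    t0 = time.time()
    out_dir = Path(cfg.output_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    p_seeds = root.spawn(cfg.n_participants)

    all_results, summaries = [], []
    for pid in range(cfg.n_participants):
        s_design, s_decode, s_behav = p_seeds[pid].spawn(3)
        trials = _design.generate_experiment(cfg.n_runs, seed=s_design.entropy % (2**31))
        association, results = _simulate_and_decode(cfg, pid, s_decode)
        all_results.extend(results)
        summary, _, _ = _behavior(cfg, pid, association, trials, s_behav)
        summaries.append(summary)

    frame = _mvpa.results_to_frame(all_results)
    mean_rows = frame[frame.hemisphere == "mean"]

    group = {}
    boot_seed = int(root.generate_state(1)[0] % (2**31))
    for roi_name in cfg.rois:
        group[roi_name] = {}
        for scheme in cfg.schemes:
            sel = mean_rows[(mean_rows.roi == f"{roi_name}:unrestricted")
                            & (mean_rows.scheme == scheme)]
            gs = _stats.bootstrap_test(sel["info"].to_numpy(), n_boot=cfg.n_boot,
                                       seed=boot_seed)
            curves = []
            for k in range(1, cfg.subroi_steps + 1):
                sub = mean_rows[(mean_rows.roi == f"{roi_name}:sub{k}")
                                & (mean_rows.scheme == scheme)]
                curves.append(sub.sort_values("participant")["info"].to_numpy())
            curves = np.column_stack(curves)
            tf_params = dataclasses.replace(cfg.tfce, seed=boot_seed)
            p_curve, z_curve, _ = _stats.tfce_curve_test(curves, tf_params)
            group[roi_name][scheme] = {
                "mean_info": gs.observed_mean, "ci": [gs.ci_low, gs.ci_high],
                "p_boot": gs.p_two_tailed,
                "subroi_p_tfce": [float(x) for x in p_curve],
            }

    deltas_p = np.array([s.guidance_delta_present for s in summaries])
    deltas_a = np.array([s.guidance_delta_absent for s in summaries])
    corr = _gaze.guidance_performance_correlation(summaries)
    behav = {
        "guidance_delta_present_mean": float(np.nanmean(deltas_p)),
        "guidance_delta_absent_mean": float(np.nanmean(deltas_a)),
        "guidance_present_boot": dataclasses.asdict(
            _stats.bootstrap_test(deltas_p[np.isfinite(deltas_p)], cfg.n_boot, boot_seed)),
        "guidance_absent_boot": dataclasses.asdict(
            _stats.bootstrap_test(deltas_a[np.isfinite(deltas_a)], cfg.n_boot, boot_seed)),
        "present_vs_absent": dataclasses.asdict(
            _gaze.condition_difference_test(deltas_p, deltas_a, cfg.n_boot, boot_seed)),
        "dprime_mean": float(np.mean([s.dprime for s in summaries])),
        "guidance_dprime_r_absent": corr["absent"][0],
        "guidance_dprime_p_absent": corr["absent"][1],
        "guidance_dprime_r_present": corr["present"][0],
        "guidance_dprime_p_present": corr["present"][1],
    }

    summary = {
        "package_version": anchorsearch.__version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "decoding": group,
        "behavior": behav,
        "runtime_s": None,
    }

    if cfg.searchlight.enabled:
        summary["searchlight"] = _searchlight_stage(cfg, root, out_dir if write_outputs else None)

    summary["runtime_s"] = round(time.time() - t0, 2)
    if write_outputs:
        frame.to_csv(out_dir / "decoding_results.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out_dir / "behavior.tsv", sep="\t", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _write_figures(cfg, frame, summaries, out_dir)
    return summary


def _searchlight_stage(cfg: PipelineConfig, root, out_dir):
    """Small-volume searchlight with the anchor code planted in a blob."""
    sl = cfg.searchlight
    gt = cfg.ground_truth
    shape = tuple(sl.shape)
    grid = np.indices(shape)
    blob = (np.sum((grid - np.array(sl.blob_center)[:, None, None, None]) ** 2,
                   axis=0) <= sl.blob_radius**2)
    neighborhood = _searchlight.sphere_offsets(sl.radius)
    mask = np.ones(shape, bool)
    rng = as_rng(root.spawn(1)[0])
    maps = []
    for pid in range(cfg.n_participants):
        association = _design.make_association_map(pid % 4)
        # anchor code restricted to the blob, Gaussian noise everywhere
        P_anchor = {a: rng.standard_normal(shape) * blob for a in _design.ANCHORS}
        vol = np.empty((cfg.n_runs, 4) + shape)
        for ci, (target, context) in enumerate(_synth.CONDITIONS):
            vol[:, ci] = gt.anchor_amp * P_anchor[association.anchor_for(target, context)]
        vol += rng.standard_normal(vol.shape) * gt.noise_sd
        info_map = _searchlight.run_searchlight(vol, list(_synth.CONDITIONS), mask,
                                                neighborhood, association)
        maps.append(info_map)
    maps = np.stack(maps)
    params = _stats.TfceParams(n_permutations=sl.n_permutations,
                               tail="one_sided_positive",
                               seed=int(root.generate_state(1)[0] % (2**31)))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    p, z, table = _searchlight.group_searchlight(maps, params, affine)
    if out_dir is not None:
        _searchlight.save_map(z, affine, out_dir / "searchlight_z.nii.gz")
        table.to_csv(out_dir / "searchlight_clusters.tsv", sep="\t", index=False)
    return {"n_clusters": int(len(table)),
            "clusters": table.to_dict("records")}


def _write_figures(cfg, frame, summaries, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_rows = frame[frame.hemisphere == "mean"]
    fig, axes = plt.subplots(1, len(cfg.rois), figsize=(5 * len(cfg.rois), 4),
                             squeeze=False)
    for ax, roi_name in zip(axes[0], cfg.rois):
        for scheme in cfg.schemes:
            xs, ys, es = [], [], []
            for k in range(1, cfg.subroi_steps + 1):
                sub = mean_rows[(mean_rows.roi == f"{roi_name}:sub{k}")
                                & (mean_rows.scheme == scheme)]["info"]
                xs.append(k)
                ys.append(sub.mean())
                es.append(sub.std(ddof=1) / np.sqrt(len(sub)))
            ax.errorbar(xs, ys, yerr=es, marker="o", label=scheme)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("sub-ROI step")
        ax.set_ylabel("classifier information (a.u.)")
        ax.set_title(roi_name)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "decoding_curves.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ga = [s.guidance_delta_absent for s in summaries]
    dp = [s.dprime for s in summaries]
    ax.scatter(ga, dp, s=12)
    ax.set_xlabel("guidance Δ% (target absent)")
    ax.set_ylabel("d'")
    fig.tight_layout()
    fig.savefig(out_dir / "guidance_dprime.png", dpi=120)
    plt.close(fig)
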