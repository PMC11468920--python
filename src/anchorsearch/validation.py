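"""Simulation studies validating the pipeline's statistical behavior.

These are the package's built-in recovery and calibration experiments:

- sign logic of cross-scene decoding (anchor code → positive information,
  target code → negative) with group-level detection rates,
- null calibration of the participant bootstrap and of the TFCE + max-stat
  family-wise error rate,
- recovery of the first-fixation guidance statistic and of the
  guidance–d′ correlation from the behavioral generator.

Each study is a pure function of its parameters and seed.
"""

from __future__ import annotations

import numpy as np

from anchorsearch import design as _design
from anchorsearch import gaze as _gaze
from anchorsearch import mvpa as _mvpa
from anchorsearch import stats as _stats
from anchorsearch import synth as _synth
from anchorsearch._rng import as_rng


def simulate_group_cross_scene(gt: _synth.GroundTruth, n_participants: int = 34,
                               n_voxels: int = 264, n_runs: int = 8,
                               seed=None) -> np.ndarray:
    """Per-participant cross-scene information for one synthetic cohort."""
    rng = as_rng(seed)
    infos = np.empty(n_participants)
    for pid in range(n_participants):
        association = _design.make_association_map(pid % 4)
        pats, _ = _synth.simulate_participant_betas(
            gt, association, n_runs=n_runs, n_voxels_per_hemisphere=n_voxels,
            seed=rng)
        res = _mvpa.run_scheme({h: pats[("LOC", h)] for h in ("left", "right")},
                               "anchor_cross_scene", association,
                               participant_id=pid)
        infos[pid] = res.info
    return infos


def cross_scene_detection_study(anchor_amp: float, target_amp: float,
                                n_replicates: int = 100, n_participants: int = 34,
                                n_voxels: int = 264, n_runs: int = 8,
                                noise_sd: float = 1.0, n_boot: int = 2000,
                                alpha: float = 0.05, seed=None) -> dict:
    """Replicate the group cross-scene test many times.

    Returns the per-replicate group means and bootstrap p-values plus the
    fraction of replicates detecting the effect with the expected sign
    (positive for an anchor code, negative for a target code).
    """
    rng = as_rng(seed)
    gt = _synth.GroundTruth(anchor_amp=anchor_amp, target_amp=target_amp,
                            context_amp=0.0, noise_sd=noise_sd)
    expected_sign = 1.0 if anchor_amp >= target_amp else -1.0
    means = np.empty(n_replicates)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        infos = simulate_group_cross_scene(gt, n_participants, n_voxels, n_runs,
                                           seed=rng)
        gs = _stats.bootstrap_test(infos, n_boot=n_boot,
                                   seed=int(rng.integers(2**31)))
        means[i] = gs.observed_mean
        pvals[i] = gs.p_two_tailed
    detected = (np.sign(means) == expected_sign) & (pvals < alpha)
    return {"means": means, "pvals": pvals,
            "detection_rate": float(detected.mean()),
            "expected_sign": expected_sign}


def bootstrap_null_calibration(n_sims: int = 2000, n_participants: int = 34,
                               n_boot: int = 2000, alpha: float = 0.05,
                               seed=None) -> float:
    """Two-tailed rejection rate of the participant bootstrap on pure-noise
    group datasets (standard-normal participant scores)."""
    rng = as_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        vals = rng.standard_normal(n_participants)
        gs = _stats.bootstrap_test(vals, n_boot=n_boot,
                                   seed=int(rng.integers(2**31)))
        rejections += gs.p_two_tailed < alpha
    return rejections / n_sims


def tfce_curve_fwer(n_sims: int = 400, n_participants: int = 34,
                    curve_len: int = 5, n_permutations: int = 500,
                    alpha: float = 0.05, seed=None) -> float:
    """Family-wise error rate of the sign-flip TFCE + max-stat test on
    pure-noise 1-D sub-ROI curves."""
    rng = as_rng(seed)
    family_errors = 0
    for _ in range(n_sims):
        curves = rng.standard_normal((n_participants, curve_len))
        params = _stats.TfceParams(n_permutations=n_permutations,
                                   seed=int(rng.integers(2**31)))
        p, _, _ = _stats.tfce_curve_test(curves, params)
        family_errors += bool((p < alpha).any())
    return family_errors / n_sims


def participant_behavior(gt: _synth.GroundTruth, trials, association,
                         seed=None) -> _gaze.BehavioralSummary:
    """Simulate one participant's fixations and responses, then run the
    full gaze/behavioral analysis path."""
    rng = as_rng(seed)
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
    return _gaze.behavioral_summary(0, trials, by_trial, responses, aois, association)


def guidance_recovery_study(guidance_prob: float = 0.6, n_participants: int = 34,
                            n_runs: int = 8, seed=None) -> dict:
    """Recover Δ% when every first fixation is anchor-directed.

    With landing probability p on the associated anchor, E[Δ%] = 100·(2p − 1);
    returns the cohort mean, the number of included trials and the binomial
    95% half-width of the mean estimate.
    """
    rng = as_rng(seed)
    gt = _synth.GroundTruth(guidance_prob_present=guidance_prob,
                            guidance_prob_absent=guidance_prob,
                            guidance_prob_sd=0.0, anchor_directed_prob=1.0,
                            fixation_recorded_prob=1.0, center_fixation_prob=1.0)
    trials = _design.generate_experiment(n_runs, seed=int(rng.integers(2**31)))
    deltas, n_included = [], 0
    for pid in range(n_participants):
        association = _design.make_association_map(pid % 4)
        s = participant_behavior(gt, trials, association, seed=rng)
        deltas.extend([s.guidance_delta_present, s.guidance_delta_absent])
        n_included += sum(1 for t in trials if t.trial_type == "search")
    per_trial_var = 100.0**2 * 4.0 * guidance_prob * (1 - guidance_prob)
    half_width = 1.96 * np.sqrt(per_trial_var / n_included)
    return {"mean_delta": float(np.mean(deltas)),
            "expected_delta": 100.0 * (2 * guidance_prob - 1),
            "n_included": n_included, "ci_half_width": float(half_width)}


def guidance_dprime_correlation_study(n_replicates: int = 500,
                                      n_participants: int = 34,
                                      n_runs: int = 8, gt=None,
                                      seed=None) -> np.ndarray:
    """Sample correlations between guidance Δ% (target absent) and d′
    across replicated cohorts under the default generator."""
    rng = as_rng(seed)
    gt = gt or _synth.GroundTruth()
    trials = _design.generate_experiment(n_runs, seed=int(rng.integers(2**31)))
    rs = np.empty(n_replicates)
    for i in range(n_replicates):
        summaries = []
        for pid in range(n_participants):
            association = _design.make_association_map(pid % 4)
            summaries.append(participant_behavior(gt, trials, association, seed=rng))
        corr = _gaze.guidance_performance_correlation(summaries)
        rs[i] = corr["absent"][0]
    return rs
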