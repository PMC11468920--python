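# anchorsearch

Simulation and analysis pipeline for **context-guided visual search**
experiments combining fMRI multivariate pattern analysis (MVPA) and eye
tracking.

## The scientific problem

In naturalistic search, attention is often guided not by the target's own
features but by large, predictive **anchor objects** (looking for a pen, we
fixate the desk). In the paradigm this package models, observers search for
two target categories (books, bowls) in two scene contexts (a blue and a
yellow living room). Within each context every target always appears on one
of two tables — its anchor — and the target→anchor association *reverses*
between contexts. On *preview-only* trials observers prepare to search but no
search display appears, isolating preparatory brain activity.

The central question is whether preparatory activity in visual cortex encodes
the **target** or the context-dependent **guiding anchor**. The reversal
makes the two dissociable by *cross-scene decoding*: train a linear
classifier to separate the two associated anchors from preview-trial
activity patterns in one context and test it in the other. Because the
associations reverse,

- **positive** cross-scene performance ⇒ the pattern codes the *anchor*,
- **negative** cross-scene performance ⇒ the pattern codes the *target*.

Decoding performance is measured by **classifier information**, a
continuous distance-to-bound score: for `n` test patterns with signed
distances `d_i` to the decision boundary and true labels `l_i ∈ {−1, +1}`,

```
information = (1/n) · Σ_i  z(d_i) · l_i
```

with `z(·)` the z-score over the `n` test distances. Group inference uses
participant bootstrap tests, and threshold-free cluster enhancement (TFCE)
with sign-flip max-statistic correction for sub-ROI curves and searchlight
maps. Eye-tracking analysis quantifies overt guidance as
`Δ% = 100 · (#first fixations on the associated anchor − #on the other
anchor) / #included trials` and relates it to search sensitivity
`d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate)`.

Because the original participant data are not required, the package ships a
full synthetic generator that emulates the experiment's structure (trial
design, voxel beta patterns with additive anchor/target/context codes,
localizer betas, fixations, responses) with known ground truth, so every
stage of the analysis can be validated by parameter recovery.

## Worked example

```python
from anchorsearch import design, synth, mvpa, stats

association = design.make_association_map(0)   # book→table_1 in the blue room
gt = synth.GroundTruth(anchor_amp=0.5, target_amp=0.0, noise_sd=1.0, seed=7)

infos = []
for pid in range(34):
    pats, _ = synth.simulate_participant_betas(
        gt, association, n_runs=8, n_voxels_per_hemisphere=264, seed=pid)
    res = mvpa.run_scheme({h: pats[("LOC", h)] for h in ("left", "right")},
                          "anchor_cross_scene", association)
    infos.append(res.info)

group = stats.bootstrap_test(infos, n_boot=2000, seed=7)
print(f"group information {group.observed_mean:.3f} "
      f"CI [{group.ci_low:.3f}, {group.ci_high:.3f}] p={group.p_two_tailed:.4f}")
```

prints

```
group information 0.981 CI [0.980, 0.983] p=0.0010
```

i.e. with an anchor code planted in the patterns (amplitude 0.5 of the noise
SD per voxel) the cross-scene classifier scores far above chance: the
preparatory pattern generalizes across contexts, the signature of an anchor
template. Setting `anchor_amp=0, target_amp=0.5` instead yields the same
magnitude with a *negative* sign (a target code), and all-zero amplitudes
give information ≈ 0.

The full pipeline — localizer simulation, ROI selection, sub-ROI sweeps,
three decoding schemes, group statistics, behavioral analysis and figures —
runs from a YAML config:

```bash
anchorsearch run -c config.yaml      # or: anchorsearch simulate / validate
```

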