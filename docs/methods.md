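# Methods

This note documents the models, conventions and numerical choices behind
`anchorsearch`, and what the synthetic validation does and does not show.

## Experimental design model

A run fully crosses five binary factors — trial type (search /
preview-only), target presence, target category (book / bowl), scene
context (blue / yellow living room), and the screen side of the associated
anchor — giving exactly 32 trials per run, each factor cell once, in a
seeded random order. Eight runs yield 256 trials, 128 of them preview-only.
Target presence and anchor side are generated for preview-only trials too,
although they have no stimulus consequence there; this keeps the
five-factor counterbalancing exact, and every pairwise 2×2 cross-table of
factor levels within a run is uniform (8 per cell).

The target→anchor association map assigns each (context, target) pair an
anchor such that (i) the two targets map to distinct anchors within a
context and (ii) the mapping reverses (anchor-swap) between contexts. Four
counterbalancing variants exist: two pairings in the "primary" context
times two choices of primary context. Note that under the reversal
constraint only two distinct (context, target) → anchor functions exist;
the primary-context choice is carried explicitly so the four variants
remain distinguishable for counterbalancing bookkeeping.

Timing: 1-s word cue, then a scene preview jittered uniformly between 3.1
and 4.0 s on search trials and lasting a fixed 4.4 s on preview-only
trials; inter-trial intervals uniform 2–4 s; search trials add 1.9 s for
the brief search display and the response screen. These defaults keep a run
under the 198-scan window at TR = 1.5 s. All bounds are configurable; the
mixed jittered/fixed preview convention reconciles the two timing figures
in circulation for this paradigm and affects only boxcar lengths.

## Synthetic voxel patterns

Run-wise condition betas are generated additively per hemisphere:

```
beta(run, cond, v) = baseline
                   + anchor_amp  · P_anchor[assoc(cond)][v]
                   + target_amp  · P_target[cond.target][v]
                   + context_amp · P_context[cond.context][v]
                   + ε,    ε ~ N(0, noise_sd²) i.i.d.
```

The code patterns `P_*` are fixed, seeded random direction vectors scaled
to **unit per-voxel RMS** (Euclidean norm √n_voxels). Amplitudes are
therefore per-voxel signal standard deviations in the same units as
`noise_sd`; `anchor_amp = 0.5, noise_sd = 1` means the anchor code carries
half a noise-SD of signal per voxel. The anchor pattern is keyed by the
*associated* anchor under the association map, so the same anchor evokes
the bit-identical pattern in both contexts — exactly the structure that
cross-scene decoding detects. Hemispheres get independent patterns and
noise, mirroring the per-hemisphere classification. There are no voxel
tuning curves, spatial autocorrelation, or physiological noise: this is
the minimal structure sufficient to validate every downstream stage, and
passing tests therefore demonstrate correctness of the analysis machinery,
not sensitivity on real BOLD data.

Localizer betas cover 8 conditions (book/bowl/table 1/table 2 ×
central/peripheral). A seeded fraction of voxels carries a ±effect/2 mean
difference between books and bowls, an independent (possibly overlapping)
fraction between the tables. Localizer and task signal patterns are
independent by default, reflecting the reported absence of cross-decoding
between localizer and task.

## GLM

Condition regressors are boxcars spanning the preview, convolved with the
canonical double-gamma HRF (peak 6 s, undershoot 16 s, unit dispersions,
peak:undershoot ratio 6, 32-s kernel, unit peak) on a TR/16 grid and
sampled at scan times; the dt factor approximates the continuous-time
convolution so a sustained boxcar plateaus at the kernel integral. The
search-task model contains only preview-only trials (4 target × context
regressors of interest) plus six motion regressors and a constant; search
events remain in the implicit baseline. Betas are estimated per run by
OLS; redundant nuisance columns are dropped with a warning, rank-deficient
interest columns are an error naming the confounded conditions.

Localizer selectivity is a one-way F across condition groups with betas
averaged within (run × group) first, so each group contributes one
replicate per run and df = (k−1, k(n_runs−1)). Zero within-group variance
with distinct means is reported as F = +∞, p = 0.

## ROI selection and sub-ROIs

A participant ROI is the union of target-selective and anchor-selective
voxels (localizer contrast p < α, uncorrected, default α = 0.05) inside a
group mask, per hemisphere. Sub-ROIs of graded size
`round(k·max/n_steps)` (default 5 steps, e.g. up to 264 voxels for LOC and
424 for EVC) take the leading voxels of an *interleaved* ranking that
alternates between the target-F and anchor-F orderings, skipping voxels
already taken. This realizes the "equal number of top target- and
anchor-selective voxels" rule while handling overlap (backfilled
alternately) and guaranteeing nesting; ties break by voxel id and odd
sizes give the target ranking the extra voxel. These overlap/tie rules are
package decisions — the field convention is not standardized.

## Decoding and the information score

Linear SVMs (C = 1, scikit-learn/libsvm) are trained per hemisphere on
run-wise betas; no feature scaling is applied by default. Distances to the
decision boundary are geometric ((w·x + b)/‖w‖); the information score is
invariant to this normalization. Schemes:

- `target_loro`, `anchor_loro`: leave-one-run-out over 8 runs; test
  distances are pooled across folds and the information score computed
  once on the pooled set (the formula is written over all n test betas;
  per-fold z-scoring is available behind a flag),
- `anchor_cross_scene`: train on one context's anchor labels, test on the
  other, both directions averaged.

Hemispheres are decoded separately and averaged before group statistics.
z-scoring uses the population SD; a zero SD returns information 0 by
convention, and accuracy counts distance-0 ties as 0.5.

**Known property:** under pure noise the pooled-z LORO information score
is slightly positively biased at *small* voxel counts (≈ +0.06 at 30
voxels, 8 runs; confirmed by an independent simulation). At the study's
ROI sizes (≥ ~200 voxels), and for the cross-scene scheme at any size, the
null mean is 0 within Monte-Carlo error. Users decoding very small ROIs
should prefer permutation nulls over the nominal zero chance level.

## Group inference

Bootstrap tests resample participants with replacement (default 10000
iterations): percentile 95% CI and two-tailed
p = 2·min(#{mean\* ≤ 0}+1, #{mean\* ≥ 0}+1)/(n_boot+1), capped at 1. At
n = 34 the exact null rejection rate of this percentile test is ≈ 0.062 at
α = 0.05 — mildly anti-conservative, a known small-sample property.

TFCE enhances a statistic map as Σ_h e(h,p)^E · h^H · dh over the ladder
h = dh, 2dh, … with E = 0.5, H = 2 by default and dh = max/100 when
unspecified; adjacency is the chain for 1-D sub-ROI curves and face
connectivity for volumes. Two-sided maps enhance the negative part
separately and subtract. Closed-form limits used as oracles: E = H = 0
recovers the positive part of the map; E = 0, H = 1 integrates to m²/2.
Group maps fed to TFCE are one-sample t maps; sign-flip permutations
(default 10000; fewer in desk-scale runs) of the participant maps give the
max-TFCE null, and corrected p = (#{null_max ≥ observed}+1)/(n_perm+1)
with z = Φ⁻¹(1−p), clipped one permutation step from p = 1 to stay finite.
The sub-ROI curve test treats the 5 sizes as a 1-D map with chain
adjacency.

## Searchlight

Sphere membership is all integer offsets with ‖o‖² ≤ r² (configurable to
strict inequality); radius 5 gives 515 voxels under the ≤ convention (the
"around 524" figure of some toolboxes reflects a different membership
rule; the chosen convention is recorded in output metadata). Spheres are
clipped at volume borders and restricted to the feature mask; centers with
fewer than 2 usable voxels get a missing score. The feature mask is the
union of voxels passing a one-sided group t-test against chance (α = 0.05,
uncorrected) on either localizer decoding map, intersected with the cortex
mask. Cluster tables report peak mm coordinates through the volume affine
and volume as voxel count × |det(affine)| (8 mm³ at 2-mm isotropic
voxels).

## Behavioral generator and analysis

AOIs: center 4.5° × 10.5° at fixation; anchor AOIs 7.5° × 10.5° centered
at ±7.5° horizontally and −1.5° vertically (the printed geometry gives
sizes; the anchor centers are package defaults consistent with "slightly
below fixation, left and right periphery"). Anchors take precedence over
the center on overlap; boundaries are inclusive. A trial enters the
guidance analysis iff a fixation overlapping scene onset lies in the
center AOI; the first-fixation label is the AOI of the next fixation. The
generator produces an onset fixation (recorded with probability 0.9415,
central with probability 0.8333, matching the reported trial-retention
rates), then an anchor-directed fixation with probability 0.805 landing on
the associated anchor with the guidance probability (defaults 0.66
present / 0.62 absent, per-participant jitter SD 0.08 — chosen so the
expected Δ% and its between-participant spread match the reported ≈25/19
percentage points with SD ≈ 20), at a latency of N(229.53, 29.20²) ms
truncated at zero.

Responses follow equal-variance signal detection with an unbiased
criterion: hit rate Φ(d′/2), false-alarm rate Φ(−d′/2), and participant
d′ = 1.19 + 0.012·(Δ% − E[Δ%]) + N(0, 0.35²). The mean gives ≈72% search
accuracy; the slope and residual SD were set so the model-implied latent
correlation between guidance and d′ is ≈0.55 — estimation noise in d̂′
(128 search trials) attenuates the *sample* correlation to ≈0.45, which
the recovery study's coverage check accounts for. Extreme hit/FA rates are
corrected by the 1/(2N) rule before the Φ⁻¹ transform. The guidance–d′
relation uses Pearson r with the two-sided t-transform p (n−2 df);
present-vs-absent guidance differences use the participant bootstrap on
paired differences.

## Validation studies and problem sizes

`anchorsearch.validation` packages the recovery/calibration experiments:
cross-scene sign logic (100 cohorts of 34 participants, 264 voxels per
hemisphere, amplitude 0.5, noise SD 1 — detection rate of the correctly
signed group effect at bootstrap p < 0.05), bootstrap null calibration
(standard-normal participant scores, n_boot = 2000), TFCE family-wise
error on pure-noise 5-point curves (500 sign-flips), guidance recovery at
p = 0.6 (expected Δ% = 20), and the guidance–d′ correlation distribution
over replicated cohorts. Cohorts within a replication study share one
trial sequence — guidance statistics do not depend on trial order — and
the study sizes above keep each study in the seconds-to-minutes range on a
single CPU while leaving Monte-Carlo error small against the bands being
checked.

## Known limitations

- No spatial noise correlation, motion artifacts or physiology in the
  beta generator; searchlight and ROI results on synthetic data are best
  interpreted as machinery validation.
- The behavioral generator ties d′ to guidance through a single latent
  shift shared by present/absent conditions; real data may dissociate
  them.
- The percentile bootstrap's mild anti-conservatism at n = 34 (above) is
  inherited from the procedure itself, not corrected.
- Localizer miniblock GLM estimation is reduced to run-wise condition
  betas; slice timing, prewhitening and smoothing are out of scope.
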