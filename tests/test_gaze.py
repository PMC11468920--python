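"""AOI classification, first-fixation guidance, d' and their relations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from anchorsearch import design, gaze, synth


AOIS = gaze.AoiSet()


def fix(x, y, onset=300.0, ordinal=1, trial=0, duration=150.0):
    return gaze.FixationRecord(trial_ref=trial, x=x, y=y, onset=onset,
                               duration=duration, ordinal=ordinal)


class TestClassifyFixation:
    @pytest.mark.parametrize("point,label", [
        ((0.0, 0.0), "center"),
        ((-7.5, -1.5), "left_anchor"),
        ((7.5, -1.5), "right_anchor"),
        ((20.0, 0.0), "none"),
        ((0.0, 9.0), "none"),
    ])
    def test_reference_points(self, point, label):
        assert gaze.classify_fixation(point, AOIS) == label

    def test_boundary_inclusive(self):
        # right edge of the center AOI
        assert gaze.classify_fixation((2.25, 0.0), AOIS) == "center"
        # left edge of the right-anchor AOI
        assert gaze.classify_fixation((3.75, -1.5), AOIS) == "right_anchor"

    def test_anchor_precedence_over_center(self):
        wide = gaze.AoiSet(center_rect=gaze.Rect(0.0, 0.0, 9.0, 10.5))
        assert gaze.classify_fixation((4.0, -1.5), wide) == "right_anchor"

    def test_overlapping_anchor_aois_rejected(self):
        with pytest.raises(ValueError):
            gaze.AoiSet(left_anchor_rect=gaze.Rect(-1.0, 0.0, 7.5, 10.5),
                        right_anchor_rect=gaze.Rect(1.0, 0.0, 7.5, 10.5))


class TestFirstFixationLabels:
    def test_center_onset_then_anchor(self):
        fxs = [fix(0, 0, onset=-50, ordinal=0, duration=280),
               fix(-7.5, -1.5, onset=250, ordinal=1)]
        labels = gaze.first_fixation_labels({0: fxs}, AOIS)
        assert labels[0] == "left_anchor"

    def test_onset_outside_center_excluded(self):
        fxs = [fix(6.0, 0.0, onset=-50, ordinal=0, duration=280),
               fix(-7.5, -1.5, onset=250, ordinal=1)]
        assert gaze.first_fixation_labels({0: fxs}, AOIS)[0] == "excluded"

    def test_no_fixation_overlapping_onset_excluded(self):
        fxs = [fix(0, 0, onset=100, ordinal=0)]
        assert gaze.first_fixation_labels({0: fxs}, AOIS)[0] == "excluded"

    def test_no_subsequent_fixation_excluded(self):
        fxs = [fix(0, 0, onset=-50, ordinal=0, duration=300)]
        assert gaze.first_fixation_labels({0: fxs}, AOIS)[0] == "excluded"

    def test_tolerance_window(self):
        fxs = [fix(0, 0, onset=20, ordinal=0, duration=200),
               fix(7.5, -1.5, onset=260, ordinal=1)]
        assert gaze.first_fixation_labels({0: fxs}, AOIS)[0] == "excluded"
        assert gaze.first_fixation_labels({0: fxs}, AOIS,
                                          tolerance=25.0)[0] == "right_anchor"


class TestGuidanceDelta:
    def _trials(self):
        return design.generate_experiment(2, seed=1)

    def test_all_on_associated_anchor(self, association):
        trials = self._trials()
        labels = {t.run * 1000 + t.trial_index: f"{t.anchor_side}_anchor"
                  for t in trials if t.trial_type == "search"}
        d = gaze.guidance_delta(labels, trials, association)
        assert d["present"] == 100.0 and d["absent"] == 100.0

    def test_equal_split_zero(self, association):
        trials = [t for t in self._trials() if t.trial_type == "search"]
        labels = {}
        counters = {True: 0, False: 0}  # alternate within each condition
        for t in trials:
            i = counters[t.target_present]
            counters[t.target_present] += 1
            side = t.anchor_side if i % 2 == 0 else \
                ("left" if t.anchor_side == "right" else "right")
            labels[t.run * 1000 + t.trial_index] = f"{side}_anchor"
        d = gaze.guidance_delta(labels, self._trials(), association)
        assert d["present"] == 0.0 and d["absent"] == 0.0

    def test_counts_conserved(self, association):
        """Associated + other + elsewhere = included trials."""
        trials = self._trials()
        rng = np.random.default_rng(0)
        labels = {}
        n_inc = 0
        for t in trials:
            if t.trial_type != "search":
                continue
            lab = rng.choice(["left_anchor", "right_anchor", "none", "excluded"])
            labels[t.run * 1000 + t.trial_index] = lab
            n_inc += lab != "excluded"
        d = gaze.guidance_delta(labels, trials, association)
        for v in d.values():
            assert -100.0 <= v <= 100.0
        assert n_inc == sum(1 for v in labels.values() if v != "excluded")

    def test_anchor_swap_antisymmetry(self, association):
        """Swapping every label's side negates Δ%."""
        trials = self._trials()
        rng = np.random.default_rng(3)
        labels = {t.run * 1000 + t.trial_index:
                  rng.choice(["left_anchor", "right_anchor"])
                  for t in trials if t.trial_type == "search"}
        flip = {"left_anchor": "right_anchor", "right_anchor": "left_anchor"}
        flipped = {k: flip[v] for k, v in labels.items()}
        d1 = gaze.guidance_delta(labels, trials, association)
        d2 = gaze.guidance_delta(flipped, trials, association)
        for cond in ("present", "absent"):
            assert d1[cond] == pytest.approx(-d2[cond])

    def test_no_included_trials_warns(self, association):
        trials = self._trials()
        labels = {t.run * 1000 + t.trial_index: "excluded" for t in trials}
        with pytest.warns(UserWarning):
            d = gaze.guidance_delta(labels, trials, association)
        assert np.isnan(d["present"])

    def test_binomial_expectation(self, association):
        """guidance_prob = 0.6 with every first fixation anchor-directed
        → E[Δ%] = 100·(2·0.6 − 1) = 20."""
        gt = synth.GroundTruth(guidance_prob_present=0.6, guidance_prob_absent=0.6,
                               guidance_prob_sd=0.0, anchor_directed_prob=1.0,
                               fixation_recorded_prob=1.0, center_fixation_prob=1.0,
                               seed=0)
        trials = design.generate_experiment(8, seed=0)
        vals = []
        for s in range(30):
            fx = synth.simulate_fixations(trials, gt, seed=s)
            by_trial = {}
            for f in fx:
                by_trial.setdefault(f.trial_ref, []).append(f)
            labels = gaze.first_fixation_labels(by_trial, AOIS)
            d = gaze.guidance_delta(labels, trials, association)
            vals.extend([d["present"], d["absent"]])
        n_trials = 30 * 128  # 64 per condition per replicate, both conditions
        half_ci = 1.96 * 100 * np.sqrt(4 * 0.6 * 0.4 / n_trials)
        assert abs(np.mean(vals) - 20.0) < half_ci * 1.5


class TestDprime:
    def test_equal_rates_zero(self):
        assert gaze.dprime(8, 16, 8, 16) == pytest.approx(0.0)

    def test_inverse_normal_oracle(self):
        # h = 0.8, f = 0.2 → 2·Φ⁻¹(0.8) ≈ 1.683
        assert gaze.dprime(8, 10, 2, 10) == pytest.approx(2 * norm.ppf(0.8), abs=1e-9)
        assert gaze.dprime(8, 10, 2, 10) == pytest.approx(1.683, abs=1e-3)

    def test_extreme_rate_correction(self):
        # 16/16 hits corrected to 31/32
        expected = norm.ppf(31 / 32) - norm.ppf(0.5)
        assert gaze.dprime(16, 16, 8, 16) == pytest.approx(expected)

    @given(st.integers(1, 15), st.integers(1, 15))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity(self, h, f):
        base = gaze.dprime(h, 16, f, 16)
        assert gaze.dprime(h + 1, 16, f, 16) > base
        assert gaze.dprime(h, 16, f + 1, 16) < base


class TestGuidancePerformance:
    def _summaries(self, deltas, dprimes):
        return [gaze.BehavioralSummary(i, 0.7, 0.3, dp, g, g)
                for i, (g, dp) in enumerate(zip(deltas, dprimes))]

    def test_deterministic_increasing_relation(self):
        deltas = np.linspace(0, 40, 10)
        corr = gaze.guidance_performance_correlation(
            self._summaries(deltas, 0.5 + 0.02 * deltas))
        assert corr["absent"][0] == pytest.approx(1.0)
        assert corr["present"][0] == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        rs = []
        for _ in range(40):
            corr = gaze.guidance_performance_correlation(
                self._summaries(rng.standard_normal(20), rng.standard_normal(20)))
            rs.append(corr["absent"][0])
        assert abs(np.mean(rs)) < 0.12

    def test_condition_difference_test(self, rng):
        dp = rng.standard_normal(20) + 5.0
        da = rng.standard_normal(20)
        gs = gaze.condition_difference_test(dp, da, n_boot=999, seed=0)
        assert gs.p_two_tailed == pytest.approx(2 / 1000)
        same = gaze.condition_difference_test(da, da, n_boot=999, seed=0)
        assert same.p_two_tailed > 0.9


def test_fixation_table_roundtrip(tmp_path, association):
    gt = synth.GroundTruth(seed=5)
    trials = design.generate_experiment(2, seed=5)
    fx = synth.simulate_fixations(trials, gt, seed=5)
    path = tmp_path / "fixations.tsv"
    gaze.write_fixation_table({0: fx}, path)
    back = gaze.read_fixation_table(path)
    assert back[0] == fx
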