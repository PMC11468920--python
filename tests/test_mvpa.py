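"""Linear decoding and the classifier-information statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from anchorsearch import design, mvpa, synth


class TestClassifierInformation:
    def test_perfect_symmetric_case(self):
        assert mvpa.classifier_information([1.0, -1.0], [1, -1]) == pytest.approx(1.0)

    def test_worked_example(self):
        info = mvpa.classifier_information([2.0, 0.5, -1.0, -0.5], [1, 1, -1, -1])
        assert info == pytest.approx(0.8729, abs=1e-4)

    def test_matches_direct_formula_on_random_inputs(self, rng):
        """Cross-check against an independent, loop-based evaluation."""
        for _ in range(50):
            n = rng.integers(2, 40)
            d = rng.standard_normal(n)
            l = rng.choice([-1, 1], size=n)
            mu = sum(d) / n
            sd = (sum((x - mu) ** 2 for x in d) / n) ** 0.5
            expected = sum((x - mu) / sd * y for x, y in zip(d, l)) / n
            assert mvpa.classifier_information(d, l) == pytest.approx(expected, abs=1e-12)

    def test_label_flip_negates(self, rng):
        d = rng.standard_normal(10)
        l = rng.choice([-1, 1], size=10)
        assert mvpa.classifier_information(d, l) == pytest.approx(
            -mvpa.classifier_information(d, -l))

    @given(st.floats(0.01, 100.0), st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_positive_affine_invariance(self, scale, shift):
        d = np.array([2.0, 0.5, -1.0, -0.5])
        l = np.array([1, 1, -1, -1])
        base = mvpa.classifier_information(d, l)
        assert mvpa.classifier_information(scale * d + shift, l) == pytest.approx(base)

    def test_degenerate_and_invalid_inputs(self):
        assert mvpa.classifier_information([1.0, 1.0], [1, -1]) == 0.0
        with pytest.raises(ValueError):
            mvpa.classifier_information([1.0], [1])

    def test_all_correct_balanced_positive(self, rng):
        d = np.concatenate([rng.uniform(0.1, 2, 10), -rng.uniform(0.1, 2, 10)])
        l = np.concatenate([np.ones(10), -np.ones(10)])
        assert mvpa.classifier_information(d, l) > 0


class TestAccuracy:
    def test_all_correct(self):
        assert mvpa.accuracy_score([2, 0.5, -1, -0.5], [1, 1, -1, -1]) == 1.0

    def test_tie_counts_half(self):
        assert mvpa.accuracy_score([0.0, 1.0], [1, 1]) == 0.75

    def test_random_labels_near_half(self, rng):
        d = rng.standard_normal(4000)
        l = rng.choice([-1, 1], size=4000)
        assert abs(mvpa.accuracy_score(d, l) - 0.5) < 0.03


class TestLinearModel:
    def test_separable_pair_bisector(self):
        model = mvpa.train_linear([[1.0, 0.0], [-1.0, 0.0]], [1, -1])
        d = mvpa.decision_values(model, [[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]])
        assert d[0] > 0 > d[1]
        assert d[2] == pytest.approx(0.0, abs=1e-9)

    def test_duplicating_patterns_leaves_model_unchanged(self, rng):
        # separable classes keep the solution in the hard-margin regime,
        # where the max-margin separator is invariant to duplication
        X = np.vstack([rng.standard_normal((5, 4)) + 3.0,
                       rng.standard_normal((5, 4)) - 3.0])
        y = np.array([1] * 5 + [-1] * 5)
        m1 = mvpa.train_linear(X, y)
        m2 = mvpa.train_linear(np.vstack([X, X]), np.concatenate([y, y]))
        w1 = m1.weights / np.linalg.norm(m1.weights)
        w2 = m2.weights / np.linalg.norm(m2.weights)
        assert np.allclose(w1, w2, atol=1e-4)

    def test_margin_matches_qp_oracle(self, rng):
        """Hard-margin dual QP solved independently (SLSQP) on separable data."""
        X = np.vstack([rng.standard_normal((10, 5)) + 4.0,
                       rng.standard_normal((10, 5)) - 4.0])
        y = np.array([1.0] * 10 + [-1.0] * 10)
        model = mvpa.train_linear(X, y, C=1.0)
        d = mvpa.decision_values(model, X)
        assert np.all(np.sign(d) == y)  # zero training errors

        K = (X * y[:, None]) @ (X * y[:, None]).T

        def neg_dual(a):
            return 0.5 * a @ K @ a - a.sum()

        res = minimize(neg_dual, np.full(20, 0.01), jac=lambda a: K @ a - 1,
                       bounds=[(0, None)] * 20,
                       constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                     "jac": lambda a: y}],
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        w_oracle = ((res.x * y)[:, None] * X).sum(axis=0)
        margin_oracle = 1.0 / np.linalg.norm(w_oracle)
        margin = 1.0 / np.linalg.norm(model.weights)
        assert margin == pytest.approx(margin_oracle, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mvpa.train_linear([[1.0], [2.0]], [1, 1])

    def test_hand_computed_distance(self):
        model = mvpa.LinearModel(weights=np.array([3.0, 4.0]), bias=0.0)
        assert mvpa.decision_values(model, [[1.0, 1.0]])[0] == pytest.approx(1.4)

    def test_dimension_mismatch(self):
        model = mvpa.LinearModel(weights=np.array([1.0, 2.0]), bias=0.0)
        with pytest.raises(ValueError):
            mvpa.decision_values(model, [[1.0, 2.0, 3.0]])


class TestRunScheme:
    def _patterns(self, gt, association, seed=0, n_vox=40):
        pats, _ = synth.simulate_participant_betas(gt, association, seed=seed,
                                                   n_voxels_per_hemisphere=n_vox)
        return {h: pats[("LOC", h)] for h in ("left", "right")}

    def test_anchor_code_positive_cross_scene(self, association):
        gt = synth.GroundTruth(anchor_amp=0.6, target_amp=0.0, context_amp=0.3,
                               noise_sd=1.0, seed=1)
        infos = [mvpa.run_scheme(self._patterns(gt, association, seed=s),
                                 "anchor_cross_scene", association).info
                 for s in range(8)]
        assert np.mean(infos) > 0.15

    def test_target_code_negative_cross_scene(self, association):
        gt = synth.GroundTruth(anchor_amp=0.0, target_amp=0.6, context_amp=0.3,
                               noise_sd=1.0, seed=2)
        infos = [mvpa.run_scheme(self._patterns(gt, association, seed=s),
                                 "anchor_cross_scene", association).info
                 for s in range(8)]
        assert np.mean(infos) < -0.15

    def test_loro_recovers_matching_code(self, association):
        gt = synth.GroundTruth(anchor_amp=0.6, target_amp=0.0, context_amp=0.0,
                               noise_sd=1.0, seed=3)
        pats = self._patterns(gt, association, seed=3)
        anchor = mvpa.run_scheme(pats, "anchor_loro", association)
        target = mvpa.run_scheme(pats, "target_loro", association)
        assert anchor.info > 0.3
        assert abs(target.info) < abs(anchor.info)

    def test_context_swap_symmetry(self, quiet_gt, association):
        """Cross-scene averaging makes the result independent of which
        context is called 'train' first (both directions always run)."""
        gt = synth.GroundTruth(anchor_amp=0.5, target_amp=0.2, context_amp=0.3,
                               noise_sd=1.0, seed=4)
        pats = self._patterns(gt, association, seed=4, n_vox=20)
        r1 = mvpa.run_scheme(pats, "anchor_cross_scene", association)
        swap = {"blue": "yellow", "yellow": "blue"}
        relabeled = {h: synth.BetaPatterns(values=bp.values.copy(),
                                           condition_labels=[(t, swap[c]) for t, c
                                                             in bp.condition_labels],
                                           hemisphere=h, roi_name=bp.roi_name,
                                           voxel_ids=bp.voxel_ids)
                     for h, bp in pats.items()}
        # map id 2 swaps the context roles of map id 0, so the relabeled data
        # pose the physically identical problem with contexts renamed
        r2 = mvpa.run_scheme(relabeled, "anchor_cross_scene",
                             design.make_association_map(2))
        assert r2.info == pytest.approx(r1.info)

    def test_no_structure_near_zero_information(self, association, rng):
        """Pure-noise patterns at the study's ROI dimensionality carry no
        decodable structure: mean information within Monte-Carlo error of 0.
        (At much smaller voxel counts the pooled-z LORO score has a small
        positive null bias; see the methods note.)"""
        gt = synth.GroundTruth(anchor_amp=0.0, target_amp=0.0, context_amp=0.0,
                               noise_sd=1.0, seed=5)
        infos = [mvpa.run_scheme(self._patterns(gt, association, seed=s, n_vox=264),
                                 "anchor_loro", association).info for s in range(12)]
        assert abs(np.mean(infos)) < 0.12

    def test_empty_roi_rejected(self, quiet_gt, association):
        pats = self._patterns(quiet_gt, association, n_vox=10)
        empty = {h: bp.subset(np.array([], dtype=int)) for h, bp in pats.items()}
        with pytest.raises(ValueError):
            mvpa.run_scheme(empty, "anchor_loro", association)

    def test_hemisphere_averaging(self, quiet_gt, association):
        pats = self._patterns(quiet_gt, association, n_vox=15)
        res = mvpa.run_scheme(pats, "anchor_loro", association)
        hem = [v["info"] for v in res.per_hemisphere.values()]
        assert res.info == pytest.approx(np.mean(hem))
        assert set(res.per_hemisphere) == {"left", "right"}


def test_results_frame_layout(quiet_gt, association):
    pats, _ = synth.simulate_participant_betas(quiet_gt, association,
                                               n_voxels_per_hemisphere=10)
    res = mvpa.run_scheme({h: pats[("LOC", h)] for h in ("left", "right")},
                          "anchor_loro", association, participant_id=0)
    df = mvpa.results_to_frame([res])
    assert set(df.columns) == {"participant", "roi", "roi_size", "hemisphere",
                               "scheme", "info", "accuracy"}
    assert set(df.hemisphere) == {"left", "right", "mean"}
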