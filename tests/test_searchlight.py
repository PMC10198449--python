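import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfrsa import modelrsm, synthgen
from selfrsa.searchlight import (
    SearchlightSpec,
    neural_rsm,
    rsa_regression,
    run_searchlight,
    sphere_offsets,
    vif,
)


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(1, 7), (2, 33), (3, 123)])
    def test_lattice_counts(self, radius, count):
        assert len(sphere_offsets(radius)) == count

    def test_includes_origin(self):
        assert (sphere_offsets(2) == 0).all(axis=1).any()

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(0.5, 5.0))
    def test_count_nondecreasing_and_symmetric(self, radius):
        off = sphere_offsets(radius)
        assert len(off) <= len(sphere_offsets(radius + 0.5))
        as_set = {tuple(o) for o in off}
        for o in off:
            assert (-o[0], -o[1], -o[2]) in as_set          # sign flip
            for perm in itertools.permutations(o):          # axis permutation
                assert tuple(perm) in as_set

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(0)


class TestNeuralRsm:
    def test_identical_patterns_clip_at_positive_extreme(self, rng):
        a = rng.standard_normal(10)
        z = neural_rsm(np.vstack([a, a]))
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_anticorrelated_patterns_clip_at_negative_extreme(self, rng):
        a = rng.standard_normal(10)
        b = -(a - a.mean()) + 5.0
        z = neural_rsm(np.vstack([a, b]))
        assert z[0, 1] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_matches_corrcoef_then_atanh_oracle(self, rng):
        x = rng.standard_normal((6, 10))
        z = neural_rsm(x)
        oracle = np.arctanh(np.clip(np.corrcoef(x), -(1 - 1e-7), 1 - 1e-7))
        i, j = np.tril_indices(6, k=-1)
        np.testing.assert_allclose(z[i, j], oracle[i, j], atol=1e-12)
        # spot value: atanh(0.5) = 0.5493
        assert np.arctanh(0.5) == pytest.approx(0.54930614, abs=1e-8)

    def test_zero_variance_item_marked_missing(self, rng):
        x = rng.standard_normal((4, 8))
        x[2] = 3.0
        z = neural_rsm(x)
        assert np.isnan(z[2, 0]) and np.isnan(z[0, 2])
        assert np.isfinite(z[1, 0])


class TestRsaRegression:
    @pytest.fixture()
    def predictors(self, rng):
        rsms = [modelrsm.build_model_rsm(rng.integers(1, 8, 12), "rating7",
                                         f"d{k}") for k in range(3)]
        return modelrsm.standardize_predictors(rsms)

    def test_exact_fit_recovers_unit_coefficient(self, predictors):
        y = predictors.matrix[:, 1].copy()
        beta = rsa_regression(y, predictors)
        assert beta[2] == pytest.approx(1.0, abs=1e-10)
        assert abs(beta[1]) < 1e-10 and abs(beta[3]) < 1e-10

    def test_constant_neural_vector_loads_on_intercept(self, predictors):
        y = np.full(predictors.n_pairs, 0.7)
        beta = rsa_regression(y, predictors)
        assert beta[0] == pytest.approx(0.7, abs=1e-10)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, predictors, rng):
        y = rng.standard_normal(predictors.n_pairs)
        beta = rsa_regression(y, predictors)
        x = np.column_stack([np.ones(predictors.n_pairs), predictors.matrix])
        oracle = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_invariant_to_predictor_order(self, predictors, rng):
        y = rng.standard_normal(predictors.n_pairs)
        beta = rsa_regression(y, predictors)
        perm = [2, 0, 1]
        shuffled = modelrsm.PredictorSet(
            predictors.matrix[:, perm],
            [predictors.labels[i] for i in perm], [])
        beta_s = rsa_regression(y, shuffled)
        np.testing.assert_allclose(beta_s[1:], beta[1:][perm], atol=1e-10)

    def test_listwise_deletion_of_missing_pairs(self, predictors, rng):
        y = predictors.matrix[:, 0].copy()
        y[:5] = np.nan
        beta = rsa_regression(y, predictors)
        assert beta[1] == pytest.approx(1.0, abs=1e-6)

    def test_too_few_pairs_rejected(self, predictors):
        y = np.full(predictors.n_pairs, np.nan)
        y[:3] = 1.0
        with pytest.raises(ValueError, match="too few"):
            rsa_regression(y, predictors)


class TestVif:
    def test_orthogonal_predictors_give_unit_vif(self):
        n = 64
        x = np.zeros((n, 2))
        x[:, 0] = np.tile([1.0, -1.0], n // 2)
        x[:, 1] = np.repeat([1.0, -1.0], n // 2)
        np.testing.assert_allclose(vif(x), [1.0, 1.0], atol=1e-10)

    def test_duplicated_predictor_flagged_infinite(self, rng):
        a = rng.standard_normal(50)
        assert np.isinf(vif(np.c_[a, a])).all()

    def test_bivariate_closed_form(self):
        # two predictors with r = 0.6 -> VIF = 1/(1-0.36) = 1.5625
        rng = np.random.default_rng(5)
        a = rng.standard_normal(100_000)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(100_000)
        r = np.corrcoef(a, b)[0, 1]
        expect = 1.0 / (1.0 - r**2)
        np.testing.assert_allclose(vif(np.c_[a, b]), [expect, expect],
                                   rtol=1e-10)
        assert expect == pytest.approx(1.5625, abs=0.01)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )

        x = rng.standard_normal((200, 4))
        x[:, 3] = 0.5 * x[:, 0] + rng.standard_normal(200)
        xc = np.column_stack([x, np.ones(200)])  # statsmodels wants a const
        oracle = [variance_inflation_factor(xc, j) for j in range(4)]
        np.testing.assert_allclose(vif(x), oracle, rtol=1e-8)


class TestRunSearchlight:
    def test_exp1_configuration_yields_14_maps(self, exp1_cohort):
        ratings, cohort, truth = exp1_cohort
        preds = modelrsm.standardize_predictors(
            modelrsm.model_rsms_for_participant(ratings, 1))
        bm = run_searchlight(cohort[0], preds)
        assert bm.n_maps == 14
        assert len(bm.predictor_labels) == 7 and bm.tasks == ("self", "word")

    def test_noiseless_signal_recovered_at_roi_centers(self, small_mask):
        ratings = synthgen.generate_ratings(1, 20, seed=31)
        roi = synthgen.sphere_roi(small_mask, 3.0)
        truth = synthgen.GroundTruth("self_importance", 1.0, roi, seed=31)
        pats = synthgen.generate_item_patterns(ratings, small_mask, truth,
                                               noise_sd=0.0, n_runs=1)
        preds = modelrsm.standardize_predictors(
            modelrsm.model_rsms_for_participant(ratings, 1))
        bm = run_searchlight(pats, preds, spec=SearchlightSpec(radius=2.0,
                                                               min_voxels=8))
        enc = bm.maps[("self", "self_importance")]
        center = np.array(np.nonzero(roi)).T.mean(axis=0).round().astype(int)
        assert enc[tuple(center)] > 0.1
        others = [bm.maps[("self", lab)][tuple(center)]
                  for lab in bm.predictor_labels if lab != "self_importance"]
        assert np.nanmax(np.abs(others)) < np.abs(enc[tuple(center)])

    def test_edge_centers_below_min_count_are_nan(self, small_mask, exp1_cohort):
        ratings, cohort, _ = exp1_cohort
        preds = modelrsm.standardize_predictors(
            modelrsm.model_rsms_for_participant(ratings, 1))
        spec = SearchlightSpec(radius=3.0, min_voxels=60)
        bm = run_searchlight(cohort[0], preds, spec=spec)
        assert (~bm.valid & small_mask.data).any()  # some edges invalid
        enc = bm.maps[("self", "self_importance")]
        assert np.isnan(enc[~bm.valid]).all()
        assert np.isfinite(enc[bm.valid]).all()

    def test_permuted_item_labels_destroy_encoding_effect(self, small_mask):
        """Shuffling which item goes with which rating severs the model-RSM
        link, so ROI betas should be centred on zero."""
        roi = synthgen.sphere_roi(small_mask, 3.0)
        vals = []
        for seed in range(12):
            ratings = synthgen.generate_ratings(1, 12, seed=seed)
            truth = synthgen.GroundTruth("self_importance", 1.0, roi, seed=seed)
            pats = synthgen.generate_item_patterns(
                ratings, small_mask, truth, noise_sd=0.5, n_runs=2)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(pats.data.shape[2])
            pats.data = pats.data[:, :, perm]
            preds = modelrsm.standardize_predictors(
                modelrsm.model_rsms_for_participant(ratings, 1))
            bm = run_searchlight(pats, preds,
                                 spec=SearchlightSpec(radius=2.0, min_voxels=8))
            enc = bm.maps[("self", "self_importance")]
            vals.append(np.nanmean(enc[roi]))
        from scipy import stats as sps
        t = sps.ttest_1samp(vals, 0.0)
        assert t.pvalue > 0.01

    def test_identical_runs_give_identical_beta_maps(self, small_mask):
        ratings = synthgen.generate_ratings(1, 10, seed=33)
        roi = synthgen.sphere_roi(small_mask, 3.0)
        truth = synthgen.GroundTruth("self_importance", 1.0, roi, seed=33)
        pats = synthgen.generate_item_patterns(ratings, small_mask, truth,
                                               noise_sd=0.4, n_runs=1)
        doubled = synthgen.PatternSet(
            1, pats.tasks, pats.item_ids,
            np.concatenate([pats.data, pats.data], axis=1), small_mask)
        preds = modelrsm.standardize_predictors(
            modelrsm.model_rsms_for_participant(ratings, 1))
        spec = SearchlightSpec(radius=2.0, min_voxels=8)
        bm1 = run_searchlight(pats, preds, spec=spec)
        bm2 = run_searchlight(doubled, preds, spec=spec)
        for key in bm1.maps:
            np.testing.assert_allclose(bm1.maps[key], bm2.maps[key],
                                       atol=1e-10)
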