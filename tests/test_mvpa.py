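import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from selfrsa import mvpa
from selfrsa.groupinfer import GroupTestSpec
from selfrsa.iohub import MaskVolume, isotropic_affine
from selfrsa.mvpa import (
    consistency_anova,
    leave_one_pair_out_cv,
    lopo_roi,
    permutation_pvalue,
    svm_train_predict,
    tertile_bins,
    within_condition_consistency,
)


class TestTertileBins:
    def test_exact_tertiles(self):
        ratings = pd.Series([1, 2, 3, 5, 6, 7])
        bins = tertile_bins(ratings, ratings)
        assert sorted(bins.sizes().values()) == [2, 2, 2]

    def test_minimax_matches_brute_force_over_random_distributions(self):
        """The chosen thresholds minimize the spread of bin sizes over all
        threshold pairs (independent enumeration oracle)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ratings = pd.Series(rng.integers(1, 8, size=40))
            bins = tertile_bins(ratings, ratings)
            sizes = bins.sizes()
            spread = max(sizes.values()) - min(sizes.values())
            best = min(
                max(c) - min(c)
                for t1, t2 in itertools.combinations(range(1, 7), 2)
                for c in [[int((ratings <= t1).sum()),
                           int(((ratings > t1) & (ratings <= t2)).sum()),
                           int((ratings > t2).sum())]]
            )
            assert spread == best

    def test_uniform_forty_items_best_achievable_split(self):
        # forty items cycling 1..7 have level counts [6,6,6,6,6,5,5]; the
        # best threshold split is then 12/12/16 (spread 4)
        ratings = pd.Series((np.arange(40) % 7) + 1)
        bins = tertile_bins(ratings, ratings)
        assert sorted(bins.sizes().values()) == [12, 12, 16]

    def test_same_thresholds_applied_to_friend_ratings(self):
        rng = np.random.default_rng(3)
        self_r = pd.Series(rng.integers(1, 8, 40))
        friend_r = pd.Series(rng.integers(1, 8, 40))
        bins = tertile_bins(self_r, friend_r)
        expect = pd.Series("middle", index=friend_r.index)
        expect[friend_r <= bins.t1] = "low"
        expect[friend_r > bins.t2] = "high"
        pd.testing.assert_series_equal(bins.friend_levels, expect)

    def test_degenerate_distribution_flagged(self):
        bins = tertile_bins(pd.Series([4] * 40), pd.Series([4] * 40))
        assert bins.degenerate
        assert bins.self_levels.nunique() == 1  # single bin, best effort


class TestLopoRoi:
    @staticmethod
    def _mask():
        return MaskVolume(np.ones((10, 10, 10), dtype=bool),
                          isotropic_affine(3.0))

    def test_exchangeable_maps_give_identical_rois(self, rng):
        """When every participant carries the same dominant peak, leaving any
        one participant out must not move the ROI."""
        mask = self._mask()
        base = np.zeros(mask.shape)
        base[5, 5, 5] = 3.0
        base[4:7, 4:7, 4:7] += 1.0
        maps = [base + 0.2 * rng.standard_normal(mask.shape)
                for _ in range(9)]
        spec = GroupTestSpec(n_permutations=256, voxel_p=0.05, seed=0)
        rois = [lopo_roi(i, maps, mask, (5, 5, 5), spec) for i in range(9)]
        assert all(roi.center == (5, 5, 5) for roi in rois)
        for roi in rois[1:]:
            np.testing.assert_array_equal(roi.voxel_indices,
                                          rois[0].voxel_indices)

    def test_center_never_beyond_search_radius(self, rng):
        mask = self._mask()
        spec = GroupTestSpec(n_permutations=128, voxel_p=0.05, seed=1)
        for seed in range(5):
            r = np.random.default_rng(seed)
            maps = [r.standard_normal(mask.shape) for _ in range(8)]
            roi = lopo_roi(0, maps, mask, (5, 5, 5), spec,
                           search_radius_mm=30.0)
            dist_mm = 3.0 * np.linalg.norm(np.array(roi.center) - 5)
            assert dist_mm <= 30.0

    def test_roi_within_mask_and_bounded_size(self, rng):
        data = rng.random((10, 10, 10)) > 0.3
        data[5, 5, 5] = True
        mask = MaskVolume(data, isotropic_affine(3.0))
        spec = GroupTestSpec(n_permutations=128, voxel_p=0.05, seed=2)
        maps = [rng.standard_normal(mask.shape) for _ in range(8)]
        roi = lopo_roi(0, maps, mask, (5, 5, 5), spec)
        assert len(roi.voxel_indices) <= 123
        assert mask.data[tuple(roi.voxel_indices.T)].all()

    def test_centers_recover_true_signal_region(self):
        """With a strong common activation blob, left-out ROI centers land
        inside the blob across seeds."""
        mask = self._mask()
        blob = np.zeros(mask.shape)
        blob[4:7, 4:7, 4:7] = 1.5
        spec = GroupTestSpec(n_permutations=256, voxel_p=0.01, seed=0)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            maps = [blob + 0.6 * r.standard_normal(mask.shape)
                    for _ in range(8)]
            roi = lopo_roi(0, maps, mask, (5, 5, 5), spec)
            hits += int(blob[roi.center] > 0)
        assert hits >= 0.9 * n_seeds

    def test_too_few_remaining_rejected(self, rng):
        mask = self._mask()
        maps = [rng.standard_normal(mask.shape) for _ in range(3)]
        with pytest.raises(ValueError, match="remaining"):
            lopo_roi(0, maps, mask, (5, 5, 5),
                     GroupTestSpec(n_permutations=128))


class TestSvm:
    def test_separable_clusters_classified_perfectly(self, rng):
        train_x = np.vstack([rng.normal(-2, 0.1, (10, 4)),
                             rng.normal(2, 0.1, (10, 4))])
        train_y = np.array(["a"] * 10 + ["b"] * 10)
        test_x = np.vstack([rng.normal(-2, 0.1, (5, 4)),
                            rng.normal(2, 0.1, (5, 4))])
        pred = svm_train_predict(train_x, train_y, test_x)
        assert (pred == np.array(["a"] * 5 + ["b"] * 5)).all()

    def test_boundary_tie_goes_to_positive_class(self):
        train_x = np.array([[-1.0, 0.0], [1.0, 0.0]])
        train_y = np.array(["a", "b"])
        pred = svm_train_predict(train_x, train_y, np.array([[0.0, 0.0]]))
        assert pred[0] == "b"    # classes_[1], the lexicographically larger

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            svm_train_predict(np.ones((4, 2)), np.array(["a"] * 4),
                              np.ones((1, 2)))

    def test_weights_match_dual_qp_oracle(self):
        """Solve the soft-margin SVM dual directly with SLSQP on a 6-point
        toy and compare the primal weight vector."""
        x = np.array([[1.0, 1.0], [2.0, 0.5], [1.5, 2.0],
                      [-1.0, -0.5], [-2.0, -1.5], [-0.5, -2.0]])
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        c = 1.0
        gram = (y[:, None] * x) @ (y[:, None] * x).T

        def neg_dual(alpha):
            return 0.5 * alpha @ gram @ alpha - alpha.sum()

        res = optimize.minimize(
            neg_dual, np.full(6, 0.1), method="SLSQP",
            bounds=[(0.0, c)] * 6,
            constraints={"type": "eq", "fun": lambda a: a @ y},
            options={"ftol": 1e-14, "maxiter": 500})
        w_oracle = ((res.x * y)[:, None] * x).sum(axis=0)

        from sklearn.svm import SVC
        clf = SVC(kernel="linear", C=c).fit(x, y)
        np.testing.assert_allclose(clf.coef_.ravel(), w_oracle, atol=1e-6)


class TestLeaveOnePairOutCv:
    def test_fold_bookkeeping(self, rng):
        a = rng.standard_normal((6, 10))
        b = rng.standard_normal((6, 10))
        cv = leave_one_pair_out_cv(a, b, level="high")
        assert len(cv.fold_accuracies) == 6
        assert 0.0 <= cv.mean_accuracy_pct <= 100.0
        assert cv.cost == 1.0

    def test_chance_level_on_exchangeable_noise(self):
        accs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = r.standard_normal((6, 20))
            b = r.standard_normal((6, 20))
            accs.append(leave_one_pair_out_cv(a, b).mean_accuracy_pct)
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_distinct_patterns_classified_above_90(self, rng):
        base_a = rng.standard_normal(20)
        base_b = rng.standard_normal(20)
        a = base_a + 0.1 * rng.standard_normal((6, 20))
        b = base_b + 0.1 * rng.standard_normal((6, 20))
        cv = leave_one_pair_out_cv(a, b)
        assert cv.mean_accuracy_pct > 90.0

    def test_accuracy_monotone_in_separation(self):
        r = np.random.default_rng(0)
        sep_means = []
        for sep in (0.0, 0.5, 1.5):
            accs = []
            for seed in range(15):
                rs = np.random.default_rng(1000 + seed)
                direction = rs.standard_normal(20)
                direction /= np.linalg.norm(direction)
                a = sep * direction + rs.standard_normal((6, 20))
                b = -sep * direction + rs.standard_normal((6, 20))
                accs.append(leave_one_pair_out_cv(a, b).mean_accuracy_pct)
            sep_means.append(np.mean(accs))
        assert sep_means[0] - 8 <= sep_means[1] <= sep_means[2] + 8
        assert sep_means[2] > sep_means[0]


class TestPermutationPvalue:
    def test_observed_above_all_null_gives_minimum_p(self, rng):
        # an observed accuracy strictly above every attainable null accuracy
        # must give exactly 1/(n_perm + 1)
        a = rng.standard_normal((6, 15))
        b = rng.standard_normal((6, 15))
        p, sig = permutation_pvalue(a, b, 100.5, n_perm=100, seed=0)
        assert p == pytest.approx(1 / 101)
        assert sig

    def test_strong_separation_is_significant(self, rng):
        base_a, base_b = rng.standard_normal(15), rng.standard_normal(15)
        a = base_a + 0.05 * rng.standard_normal((6, 15))
        b = base_b + 0.05 * rng.standard_normal((6, 15))
        cv = leave_one_pair_out_cv(a, b)
        assert cv.mean_accuracy_pct == 100.0
        p, _ = permutation_pvalue(a, b, cv.mean_accuracy_pct, n_perm=100,
                                  seed=0)
        assert p < 0.05

    def test_null_observed_gives_large_p(self, rng):
        a = rng.standard_normal((6, 15))
        b = rng.standard_normal((6, 15))
        p, sig = permutation_pvalue(a, b, 50.0, n_perm=100, seed=1)
        assert p > 0.2
        assert not sig

    def test_bonferroni_threshold_is_alpha_over_comparisons(self, rng):
        a = rng.standard_normal((6, 15))
        b = rng.standard_normal((6, 15))
        p, sig = permutation_pvalue(a, b, 100.0, n_perm=60, seed=2)
        assert sig == (p < 0.05 / 3)

    def test_tiny_permutation_count_rejected(self, rng):
        a = rng.standard_normal((6, 5))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_pvalue(a, a, 50.0, n_perm=10)


def _rm_anova_oracle(table):
    """Two-way within-subject ANOVA from explicit sums of squares."""
    wide = table.pivot_table(index="participant_id", columns=["task", "level"],
                             values="mean_z")
    y = wide.to_numpy()
    n = y.shape[0]
    tasks = wide.columns.get_level_values(0).unique()
    levels = wide.columns.get_level_values(1).unique()
    a, b = len(tasks), len(levels)
    cube = y.reshape(n, a, b)
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = (resid ** 2).sum()
    f_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


class TestConsistency:
    def test_identical_runs_give_clipped_max_z(self, rng):
        run = rng.standard_normal(30)
        runs = np.tile(run, (6, 1))
        table = within_condition_consistency({("self", "high"): runs})
        assert table["n_pairs"].iloc[0] == 15
        assert table["mean_z"].iloc[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_fifteen_run_pairs_per_condition(self, rng):
        conds = {(t, lv): rng.standard_normal((6, 12))
                 for t in ("self", "other") for lv in mvpa.LEVELS}
        table = within_condition_consistency(conds)
        assert (table["n_pairs"] == 15).all()
        assert len(table) == 6

    def test_constant_run_rejected(self, rng):
        runs = rng.standard_normal((6, 12))
        runs[2] = 4.0
        with pytest.raises(ValueError, match="constant pattern"):
            within_condition_consistency({("self", "low"): runs})

    def test_anova_matches_sums_of_squares_oracle(self, rng):
        rows = []
        for pid in range(1, 11):
            for task in ("self", "other"):
                for lv in mvpa.LEVELS:
                    rows.append({"participant_id": pid, "task": task,
                                 "level": lv,
                                 "mean_z": rng.standard_normal()
                                 + (0.3 if task == "self" else 0.0)})
        table = pd.DataFrame(rows)
        res = consistency_anova(table)
        f_a, f_b, f_ab = _rm_anova_oracle(table)
        assert res.loc["task", "F"] == pytest.approx(f_a, abs=1e-8)
        assert res.loc["level", "F"] == pytest.approx(f_b, abs=1e-8)
        assert res.loc["task x level", "F"] == pytest.approx(f_ab, abs=1e-8)

    def test_no_condition_differences_give_small_f(self, rng):
        rows = []
        for pid in range(1, 13):
            offset = rng.standard_normal() * 0.5  # subject effect only
            for task in ("self", "other"):
                for lv in mvpa.LEVELS:
                    rows.append({"participant_id": pid, "task": task,
                                 "level": lv,
                                 "mean_z": offset + 0.01 * rng.standard_normal()})
        res = consistency_anova(pd.DataFrame(rows))
        assert res.loc["task", "p"] > 0.01 or res.loc["task", "F"] < 10
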