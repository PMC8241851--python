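"""Paired tests, effect sizes, repeated-measures ANOVA, SVM, and CCA."""

import numpy as np
import pytest

from dynconn import stats as dstats


class TestEffectSizes:
    def test_pooled_d_from_group_summaries(self):
        # reaction-time group statistics: 966 +/- 149 vs 738 +/- 136 ms
        d = dstats.cohen_d_pooled(966, 149, 738, 136)
        assert round(d, 1) == 1.6

    def test_d_from_paired_t(self):
        # t = 29.06 with n = 737 paired observations
        assert round(dstats.cohen_d_from_t(29.06, 737), 2) == 1.07


class TestPairedTestsFDR:
    def test_identical_samples_zero_t_and_d(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        res = dstats.paired_tests_fdr(x, x.copy())
        np.testing.assert_array_equal(res["t"], 0.0)
        np.testing.assert_array_equal(res["d_pooled"], 0.0)

    def test_bh_step_up_example(self):
        # p = (.001, .02, .03, .04) with m = 4 at q = .05: the largest k
        # with p_(k) <= k q / m is 4, so all four are rejected
        rng = np.random.default_rng(1)
        n = 1000
        targets = [0.001, 0.02, 0.03, 0.04]
        from scipy import stats as sps

        # build paired data whose t-test p-values hit the targets exactly
        v1 = np.zeros((n, 4))
        v2 = np.zeros((n, 4))
        base = rng.normal(size=n)
        base = (base - base.mean()) / base.std(ddof=1)
        for k, p in enumerate(targets):
            t_needed = sps.t.isf(p / 2, n - 1)
            shift = t_needed / np.sqrt(n)
            v1[:, k] = base + shift
        res = dstats.paired_tests_fdr(v1, v2)
        np.testing.assert_allclose(res["p"], targets, atol=1e-12)
        assert (res["q_fdr"] <= 0.05).all()

    def test_bh_matches_exhaustive_step_up_reference(self):
        # independent oracle: direct step-up scan over sorted p-values
        rng = np.random.default_rng(2)
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            m = rng.integers(1, 21)
            p = rng.uniform(0, 1, m)
            alpha = 0.05
            order = np.argsort(p)
            thresh = alpha * (np.arange(1, m + 1)) / m
            passed = np.where(p[order] <= thresh)[0]
            expect = np.zeros(m, bool)
            if passed.size:
                expect[order[: passed.max() + 1]] = True
            got, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
            np.testing.assert_array_equal(got, expect)

    def test_requires_pairing(self):
        with pytest.raises(ValueError):
            dstats.paired_tests_fdr(np.zeros((5, 2)), np.zeros((6, 2)))


class TestRMAnova:
    def test_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 2, 1))
        res = dstats.rm_anova(x)
        from scipy import stats as sps

        t = sps.ttest_rel(x[:, 0, 0], x[:, 1, 0]).statistic
        assert res["F"].iloc[0] == pytest.approx(t**2, abs=1e-8)

    def test_constant_factor_f_zero(self):
        rng = np.random.default_rng(4)
        per_subject = rng.normal(size=(12, 1, 1))
        x = np.tile(per_subject, (1, 3, 1))  # no variation across factor A
        res = dstats.rm_anova(x)
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_planted_main_effect_power(self):
        # load effect Delta = 1 at noise sd 1, n = 60: the main effect should
        # be detected at p < .01 in nearly every replicate
        rng = np.random.default_rng(5)
        hits = 0
        reps = 40
        for _ in range(reps):
            x = rng.normal(size=(60, 2, 3))
            x[:, 1, :] += 1.0
            res = dstats.rm_anova(x)
            p_load = res.set_index("effect")["p"]["A"]
            hits += p_load < 0.01
        assert hits / reps >= 0.95

    def test_interaction_reported(self):
        x = np.random.default_rng(6).normal(size=(10, 2, 2))
        res = dstats.rm_anova(x)
        assert set(res["effect"]) == {"A", "B", "A * B"}


class TestSVM:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y, 10.0, -10.0)
        res = dstats.svm_cv_perm(X, y, k=5, n_perm=10, seed=0)
        assert res.mean_accuracy == 1.0

    def test_permutation_p_floor(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y, 5.0, -5.0)
        res = dstats.svm_cv_perm(X, y, k=4, n_perm=100, seed=1)
        assert res.permutation_p >= 1 / 101
        assert res.permutation_p == pytest.approx(1 / 101)

    def test_grouped_folds_keep_pairs_together(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(np.arange(30), 2)
        folds = dstats._grouped_folds(groups, 10, rng)
        for fold in folds:
            gs = groups[fold]
            # every group in a fold contributes both its samples
            for g in np.unique(gs):
                assert (gs == g).sum() == 2

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        y[:3] = [0, 1, 0]  # ensure both classes
        r1 = dstats.svm_cv_perm(X, y, k=5, n_perm=20, seed=3)
        r2 = dstats.svm_cv_perm(X, y, k=5, n_perm=20, seed=3)
        assert r1.mean_accuracy == r2.mean_accuracy
        np.testing.assert_array_equal(r1.null_accuracies, r2.null_accuracies)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError, match="two classes"):
            dstats.svm_cv_perm(np.zeros((10, 2)), np.zeros(10))


class TestCCA:
    def test_exact_linear_map_gives_unit_correlation(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 6))
        Y = np.column_stack([X[:, 0] + 2 * X[:, 3], X[:, 1] - X[:, 2]])
        res = dstats.cca_perm(X, Y, n_perm=50, seed=0)
        assert res.first_r == pytest.approx(1.0, abs=1e-10)

    def test_correlations_sorted_in_unit_interval(self):
        rng = np.random.default_rng(12)
        res = dstats.cca_perm(rng.normal(size=(40, 5)),
                              rng.normal(size=(40, 3)), n_perm=20, seed=1)
        r = res.correlations
        assert ((0 <= r) & (r <= 1)).all()
        assert (np.diff(r) <= 1e-12).all()

    def test_matches_sklearn_first_mode(self):
        # cross-check the QR/SVD canonical correlation against sklearn's
        # iterative CCA on a well-conditioned problem
        from sklearn.cross_decomposition import CCA

        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 4))
        Y = 0.5 * X[:, :2] + rng.normal(size=(200, 2))
        r, _, _ = dstats.canonical_correlations(X, Y)
        xs, ys = CCA(n_components=1, max_iter=2000).fit_transform(X, Y)
        r_sklearn = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
        assert r[0] == pytest.approx(r_sklearn, abs=1e-6)

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        Y = rng.normal(size=(30, 2))
        with pytest.warns(UserWarning, match="constant"):
            res = dstats.cca_perm(X, Y, n_perm=10, seed=2)
        assert res.dropped_columns == [("X", 1)]

    def test_pillai_is_sum_of_squared_correlations(self):
        rng = np.random.default_rng(15)
        res = dstats.cca_perm(rng.normal(size=(60, 5)),
                              rng.normal(size=(60, 2)), n_perm=10, seed=3)
        assert res.pillai == pytest.approx((res.correlations**2).sum())

    def test_needs_more_subjects_than_behavior_columns(self):
        with pytest.raises(ValueError, match="more subjects"):
            dstats.cca_perm(np.zeros((3, 2)), np.zeros((3, 3)))
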