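"""Group statistics: t-tests, permutation thresholds, FDR, summary ANOVA/chi2."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from trinet_eeg.inference import (
    anova_from_summary, chisq_from_counts, fdr_bh, permutation_threshold,
    ttest_ind,
)


class TestTTest:
    def test_df_is_pooled_for_forty_vs_fortytwo(self, rng):
        t, df = ttest_ind(rng.standard_normal(40), rng.standard_normal(42))
        assert df == 80

    def test_identical_groups_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, _ = ttest_ind(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        t, df = ttest_ind([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4

    def test_zero_variance_returns_nan(self):
        t, _ = ttest_ind([1.0, 1.0], [1.0, 1.0])
        assert np.isnan(t)


class TestPermutationThreshold:
    def test_exhaustive_matches_independent_enumeration(self):
        """n = 4 vs 4, one feature: p equals the exhaustive p over all 70
        label splits, recomputed here with raw loops and scipy."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = permutation_threshold(x[:, None], labels, n_perm=5000, seed=0)
        assert res.exhaustive and res.n_permutations == 70

        t_obs = abs(sstats.ttest_ind(x[:4], x[4:], equal_var=True).statistic)
        count = 0
        for combo in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in combo]
            t = abs(sstats.ttest_ind(x[list(combo)], x[rest],
                                     equal_var=True).statistic)
            if t >= t_obs - 1e-12:
                count += 1
        assert res.p_perm[0] == pytest.approx(count / 70)

    def test_huge_planted_shift_is_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(20):
            X = np.random.default_rng(s).standard_normal((40, 10))
            X[:20, 0] += 5.0
            labels = np.array(["g1"] * 20 + ["g2"] * 20)
            res = permutation_threshold(X, labels, n_perm=500, seed=s)
            hits += bool(res.sig_mask[0])
        assert hits >= 19  # > 0.95 detection

    def test_alpha_one_flags_everything(self, rng):
        X = rng.standard_normal((12, 5))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = permutation_threshold(X, labels, n_perm=200, alpha=1.0, seed=1)
        assert res.sig_mask.all()

    def test_seed_determinism_and_alpha_monotonicity(self, rng):
        X = rng.standard_normal((30, 8))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        r1 = permutation_threshold(X, labels, n_perm=300, seed=9)
        r2 = permutation_threshold(X, labels, n_perm=300, seed=9)
        assert r1.crit_t == r2.crit_t
        crits = [
            permutation_threshold(X, labels, n_perm=300, alpha=a, seed=9).crit_t
            for a in (0.01, 0.05, 0.2, 0.5)
        ]
        assert all(c1 >= c2 for c1, c2 in zip(crits, crits[1:]))

    def test_df_reported(self, rng):
        X = rng.standard_normal((82, 3))
        labels = np.array(["a"] * 40 + ["b"] * 42)
        res = permutation_threshold(X, labels, n_perm=200, seed=0)
        assert res.df == 80

    def test_requires_two_groups(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            permutation_threshold(rng.standard_normal((6, 2)),
                                  np.array(["a"] * 6), n_perm=100)


class TestFdrBH:
    def test_step_up_by_hand(self):
        mask = fdr_bh(np.array([0.001, 0.2, 0.9]), q=0.05)
        assert mask.tolist() == [True, False, False]

    def test_degenerate_inputs(self):
        assert fdr_bh(np.array([]), 0.05).size == 0
        assert not fdr_bh(np.ones(5), 0.05).any()
        assert fdr_bh(np.zeros(5), 0.05).all()

    def test_matches_manual_step_up_on_random_pvalues(self, rng):
        p = rng.uniform(size=30)
        q = 0.1
        order = np.argsort(p)
        thresh = q * (np.arange(1, 31)) / 30
        passing = np.flatnonzero(p[order] <= thresh)
        expected = np.zeros(30, dtype=bool)
        if passing.size:
            expected[order[: passing.max() + 1]] = True
        np.testing.assert_array_equal(fdr_bh(p, q), expected)


class TestSummaryStats:
    def test_age_table_reconstruction(self):
        F, df1, df2 = anova_from_summary(
            [7.92, 8.32, 8.83], [2.28, 1.45, 2.21], [40, 40, 42])
        assert df1 == 2 and df2 == 119
        assert F == pytest.approx(2.103, abs=0.02)

    def test_equal_means_give_zero(self):
        F, _, _ = anova_from_summary([5.0, 5.0], [1.0, 2.0], [10, 12])
        assert F == 0.0

    def test_two_group_anova_equals_t_squared(self, rng):
        x, y = rng.standard_normal(12), 0.5 + rng.standard_normal(15)
        t, _ = ttest_ind(x, y)
        F, _, _ = anova_from_summary(
            [x.mean(), y.mean()], [x.std(ddof=1), y.std(ddof=1)], [12, 15])
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [0.5, 0.5], [1, 10])

    def test_sex_by_group_counts(self):
        x2, df = chisq_from_counts([[25, 15], [28, 12], [23, 19]])
        assert x2 == pytest.approx(2.026, abs=1e-3)
        assert df == 2

    def test_laterality_counts(self):
        x2, df = chisq_from_counts([[10, 7, 23], [13, 14, 13]])
        assert x2 == pytest.approx(5.502, abs=1e-3)
        assert df == 2

    def test_independence_gives_zero(self):
        table = np.outer([10, 20], [3, 7])  # proportional to margins
        x2, _ = chisq_from_counts(table)
        assert x2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_from_counts([[0, 0], [5, 5]])
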