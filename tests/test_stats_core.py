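"""Unit and property tests for the univariate statistical primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from beegut import stats_core


class TestAnova:
    def test_hand_computed_f(self):
        # groups (0,1) and (2,3): SSb = 4, SSw = 1, df = (1, 2), F = 8
        res = stats_core.anova_oneway([0, 1, 2, 3], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(8.0)
        assert res.df == (1, 2)

    def test_equal_means_give_zero_f(self):
        res = stats_core.anova_oneway([0, 1, 1, 0], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_f_is_squared_t(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.7, 1, 9)
        res = stats_core.anova_oneway(
            np.concatenate([x, y]), ["x"] * 8 + ["y"] * 9
        )
        t = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_degenerate_constant_input(self):
        res = stats_core.anova_oneway([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.degenerate and res.p_value == 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            stats_core.anova_oneway([1, 2, 3], ["a", "a", "b"])

    def test_matches_scipy_oneway(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = stats_core.anova_oneway(vals, groups)
        ref = sps.f_oneway(*(vals[groups == g] for g in "abc"))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestTukey:
    def test_two_groups_equal_t_test(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        table = stats_core.tukey_hsd(np.concatenate([x, y]), ["x"] * 10 + ["y"] * 10)
        t = sps.ttest_ind(x, y)
        assert table["raw_p"].iloc[0] == pytest.approx(t.pvalue, rel=1e-6)

    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning):
            table = stats_core.tukey_hsd([1, 1, 1, 1], ["a", "a", "b", "b"])
        assert (table["adjusted_p"] == 1.0).all()

    def test_separated_groups_all_significant(self):
        vals = [0, 0.1, 0.2, 10, 10.1, 10.2, 20, 20.1, 20.2]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        table = stats_core.tukey_hsd(vals, groups)
        assert (table["adjusted_p"] < 0.01).all()

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(3)
        samples = [rng.normal(m, 1, 7) for m in (0, 0.5, 2)]
        vals = np.concatenate(samples)
        groups = np.repeat(["a", "b", "c"], 7)
        ours = stats_core.tukey_hsd(vals, groups)
        ref = sps.tukey_hsd(*samples)
        # scipy orders pairs (i, j); ours lists (a,b),(a,c),(b,c)
        for row, (i, j) in zip(ours.itertuples(), [(0, 1), (0, 2), (1, 2)]):
            assert row.raw_p == pytest.approx(ref.pvalue[i, j], abs=1e-6)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = stats_core.kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(2.4)

    def test_label_permutation_invariance(self):
        vals = [3, 1, 4, 1, 5, 9, 2, 6]
        g1 = ["a", "a", "b", "b", "a", "b", "a", "b"]
        h1 = stats_core.kruskal_wallis(vals, g1).statistic
        # swap the label names
        g2 = ["b" if g == "a" else "a" for g in g1]
        h2 = stats_core.kruskal_wallis(vals, g2).statistic
        assert h1 == pytest.approx(h2)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 5, size=24).astype(float)
        groups = np.repeat(["a", "b", "c"], 8)
        res = stats_core.kruskal_wallis(vals, groups)
        ref = sps.kruskal(*(vals[groups == g] for g in "abc"))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_heavy_separation_significant(self):
        vals = list(range(5)) + list(range(100, 105))
        res = stats_core.kruskal_wallis(vals, ["a"] * 5 + ["b"] * 5)
        assert res.p_value < 0.05

    def test_all_tied_degenerate(self):
        res = stats_core.kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert res.degenerate and res.p_value == 1.0


class TestDunn:
    def test_two_group_z_squared_is_h(self):
        vals = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        groups = ["a", "a", "a", "b", "b", "b"]
        h = stats_core.kruskal_wallis(vals, groups).statistic
        table = stats_core.dunn_test(vals, groups)
        # z^2 == tie-corrected H for k = 2
        est = table["estimate"].iloc[0]
        n = len(vals)
        se = np.sqrt(n * (n + 1) / 12 * (2 / 3))
        assert (est / se) ** 2 == pytest.approx(h)

    def test_identical_groups_p_near_one(self):
        table = stats_core.dunn_test([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert (table["adjusted_p"] > 0.95).all()

    def test_brute_force_rank_means(self):
        vals = [10, 12, 11, 30, 31, 29, 50, 52, 51]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        table = stats_core.dunn_test(vals, groups)
        # rank means: a -> 2, b -> 5, c -> 8 (ranks 1..9, no ties)
        row_ab = table[(table.group_a == "a") & (table.group_b == "b")].iloc[0]
        assert row_ab.estimate == pytest.approx(2 - 5)
        se = np.sqrt(9 * 10 / 12 * (1 / 3 + 1 / 3))
        z = 3 / se
        assert row_ab.raw_p == pytest.approx(2 * sps.norm.sf(z))


class TestWilcoxon:
    def test_exact_enumeration_small(self):
        # {1,2} vs {3,4}: 6 rank assignments, two-sided p = 1/3
        res = stats_core.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = stats_core.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.8, 1, 10)
        exact = stats_core.wilcoxon_rank_sum(x, y, exact_max_n=20)
        approx = stats_core.wilcoxon_rank_sum(x, y, exact_max_n=0)
        assert abs(exact.p_value - approx.p_value) < 0.01

    def test_exact_matches_mannwhitney(self):
        x = [1.2, 3.4, 0.5, 2.2]
        y = [4.1, 5.0, 3.9, 6.2, 2.0]
        ours = stats_core.wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, method="exact")
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestAdjustP:
    def test_bonferroni(self):
        out = stats_core.adjust_p([0.01, 0.2, 0.5, 0.9, 1.0], "bonferroni")
        assert out[0] == pytest.approx(0.05)
        assert out[-1] == 1.0

    def test_bh_hand_computed(self):
        out = stats_core.adjust_p([0.01, 0.04, 0.03], "benjamini-hochberg")
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_bh_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        bh = stats_core.adjust_p(p, "benjamini-hochberg")
        bonf = stats_core.adjust_p(p, "bonferroni")
        assert (bh <= bonf + 1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=15)
        for ours_m, sm_m in (("bonferroni", "bonferroni"), ("benjamini-hochberg", "fdr_bh")):
            ours = stats_core.adjust_p(p, ours_m)
            ref = multipletests(p, method=sm_m)[1]
            assert np.allclose(ours, ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats_core.adjust_p([0.5, 1.2], "bonferroni")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_order_preserved(self, pvals):
        adj = stats_core.adjust_p(pvals, "benjamini-hochberg")
        order_raw = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order_raw]) >= -1e-12).all()


class TestNormalityRoute:
    def test_gaussian_routes_parametric(self):
        rng = np.random.default_rng(8)
        assert stats_core.normality_route(rng.normal(size=50)) == "parametric"

    def test_lognormal_routes_nonparametric(self):
        rng = np.random.default_rng(9)
        assert stats_core.normality_route(rng.lognormal(0, 1, size=50)) == "nonparametric"

    def test_minimal_n_handled(self):
        assert stats_core.normality_route([0.0, 0.5, 1.1]) in ("parametric", "nonparametric")

    def test_constant_residuals_warn_nonparametric(self):
        with pytest.warns(UserWarning):
            assert stats_core.normality_route([1.0, 1.0, 1.0]) == "nonparametric"


class TestPermutationP:
    def test_observed_above_all(self):
        assert stats_core.permutation_p(10.0, np.zeros(100)) == 0.0

    def test_observed_equal_to_all(self):
        assert stats_core.permutation_p(1.0, np.ones(50)) == 1.0

    def test_observed_at_median(self):
        permuted = np.arange(101, dtype=float)
        assert stats_core.permutation_p(50.0, permuted) == pytest.approx(51 / 101)

    def test_plus_one_variant(self):
        assert stats_core.permutation_p(10.0, np.zeros(99), plus_one=True) == pytest.approx(
            1 / 100
        )


class TestCalibrationAndInvariance:
    def test_location_shift_invariance(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=20)
        groups = np.repeat(["a", "b"], 10)
        for fn in (stats_core.anova_oneway, stats_core.kruskal_wallis):
            s0 = fn(vals, groups).statistic
            s1 = fn(vals + 100.0, groups).statistic
            assert s0 == pytest.approx(s1)

    @pytest.mark.parametrize("test_fn", [stats_core.anova_oneway, stats_core.kruskal_wallis])
    def test_type_one_error_five_percent(self, test_fn):
        """Omnibus tests reject ~5% of Gaussian null datasets at alpha 0.05."""
        rng = np.random.default_rng(11)
        groups = np.repeat(["a", "b", "c"], 10)
        n_sims = 4000
        rejections = sum(
            test_fn(rng.normal(size=30), groups).p_value < 0.05 for _ in range(n_sims)
        )
        assert 0.04 <= rejections / n_sims <= 0.06
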