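"""Normality screening, Kruskal-Wallis and rank-based multiple comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from coexp import stats
from tests.conftest import make_labeled


class TestLilliefors:
    def test_statistic_matches_statsmodels(self):
        x = np.random.default_rng(0).normal(size=200)
        d = stats.lilliefors_statistic(x)
        d_sm, _ = sm_lilliefors(x, dist="norm", pvalmethod="table")
        assert d == pytest.approx(d_sm, abs=1e-12)

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(1).normal(10.0, 2.0, 10000)
        _, p = stats.lilliefors_test(x)
        assert p > 0.05

    def test_type_one_error_calibrated(self):
        # nominal acceptance rate is 95%; with 300 repetitions the
        # binomial SE is ~1.3%, so a well-calibrated test stays >= 92%
        rng = np.random.default_rng(2)
        n_reps = 300
        accepted = sum(
            stats.lilliefors_test(rng.normal(size=10000))[1] > 0.05 for _ in range(n_reps)
        )
        assert accepted / n_reps >= 0.92

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(-4, 1, 500), rng.normal(4, 1, 500)]
        _, p = stats.lilliefors_test(x)
        assert p < 0.05

    def test_monte_carlo_agrees_with_table(self):
        x = np.random.default_rng(4).normal(size=300)
        _, p_table = stats.lilliefors_test(x, method="table")
        _, p_mc = stats.lilliefors_test(x, method="mc", n_mc=2000, seed=5)
        # both clearly on the same side of the decision boundary
        assert (p_table > 0.05) == (p_mc > 0.05)

    def test_too_small_or_constant_errors(self):
        with pytest.raises(ValueError, match="at least 5"):
            stats.lilliefors_test([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            stats.lilliefors_test([2.0] * 10)


class TestCombinations:
    def test_cyclic_assignments_in_order(self):
        combos = stats.build_combinations(["A", "B", "C"])
        assert combos == [
            {"L1": "A", "L2": "B", "L3": "C"},
            {"L1": "B", "L2": "C", "L3": "A"},
            {"L1": "C", "L2": "A", "L3": "B"},
        ]

    def test_each_combination_uses_each_subject_once(self):
        for combo in stats.build_combinations(["X", "Y", "Z"]):
            assert sorted(combo.values()) == ["X", "Y", "Z"]

    def test_wrong_subject_count_or_duplicates_error(self):
        with pytest.raises(ValueError, match="exactly 3"):
            stats.build_combinations(["A", "B"])
        with pytest.raises(ValueError, match="distinct"):
            stats.build_combinations(["A", "A", "B"])


class TestKruskalWallis:
    def test_hand_computed_separated_groups(self):
        kw = stats.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # ranks 1..9; mean ranks 2, 5, 8; H = 12/(9*10) * 3*(9+0+9) = 7.2
        assert kw.H == pytest.approx(7.2)
        assert kw.group_mean_ranks == pytest.approx((2.0, 5.0, 8.0))
        assert kw.p_value == pytest.approx(sps.chi2.sf(7.2, 2))
        assert kw.p_value < 0.05

    def test_two_identical_groups_give_zero_h(self):
        kw = stats.kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert kw.H == pytest.approx(0.0, abs=1e-12)
        assert kw.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            sizes = rng.integers(5, 40, size=rng.integers(2, 5))
            # integer values force ties, exercising the correction
            groups = [rng.integers(0, 12, size=n).astype(float) for n in sizes]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            kw = stats.kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert kw.H == pytest.approx(ref.statistic, rel=1e-12)
            assert kw.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rank_sum_conserved_with_midranks(self):
        rng = np.random.default_rng(7)
        groups = [rng.integers(0, 5, 30).astype(float) for _ in range(3)]
        kw = stats.kruskal_wallis(groups)
        total = sum(r * n for r, n in zip(kw.group_mean_ranks, kw.n_per_group))
        n = kw.grand_n
        assert total == pytest.approx(n * (n + 1) / 2)

    def test_all_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            stats.kruskal_wallis([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])

    def test_null_rejection_rate_near_alpha(self):
        # three groups from one distribution: ~5% rejections
        rng = np.random.default_rng(8)
        n_sims, n = 400, 100
        rejections = 0
        for _ in range(n_sims):
            groups = rng.normal(size=(3, n))
            rejections += stats.kruskal_wallis(list(groups)).p_value < 0.05
        assert abs(rejections / n_sims - 0.05) < 0.025


class TestMulticompare:
    def test_separated_groups_all_pairs_significant(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(mu, 0.5, 200) for mu in (0.0, 3.0, 6.0)]
        kw = stats.kruskal_wallis(groups)
        pairs = stats.multicompare(kw)
        assert len(pairs) == 3
        assert all(p.significant for p in pairs)

    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(10)
        kw = stats.kruskal_wallis([rng.normal(size=20) for _ in range(5)])
        assert len(stats.multicompare(kw)) == 10

    def test_identically_sampled_pair_rarely_significant(self):
        rng = np.random.default_rng(11)
        false_alarms = 0
        n_runs = 20
        for _ in range(n_runs):
            a = rng.normal(size=2000)
            b = rng.normal(size=2000)
            kw = stats.kruskal_wallis([a, b, rng.normal(3.0, 1.0, 2000)])
            pair_ab = stats.multicompare(kw)[0]
            false_alarms += pair_ab.significant
        assert n_runs - false_alarms >= 0.9 * n_runs

    def test_interval_excludes_zero_iff_significant(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(0, 1), 1.0, rng.integers(10, 60)) for _ in range(3)]
            kw = stats.kruskal_wallis(groups)
            for pair in stats.multicompare(kw):
                excludes = pair.ci_low > 0 or pair.ci_high < 0
                assert excludes == pair.significant
                assert pair.ci_low <= pair.rank_diff <= pair.ci_high

    def test_group_intervals_overlap_iff_nonsignificant_equal_n(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            groups = [rng.normal(rng.uniform(0, 0.6), 1.0, 80) for _ in range(3)]
            kw = stats.kruskal_wallis(groups)
            pairs = {(p.group_a, p.group_b): p.significant for p in stats.multicompare(kw)}
            iv = stats.group_rank_intervals(kw).set_index("group")
            for (a, b), sig in pairs.items():
                disjoint = iv.loc[a, "high"] < iv.loc[b, "low"] or iv.loc[b, "high"] < iv.loc[a, "low"]
                assert disjoint == sig

    def test_bonferroni_mode_consistent(self):
        rng = np.random.default_rng(14)
        kw = stats.kruskal_wallis([rng.normal(m, 1, 50) for m in (0, 1, 2)])
        for pair in stats.multicompare(kw, bonferroni=True):
            excludes = pair.ci_low > 0 or pair.ci_high < 0
            assert excludes == pair.significant


class TestBoxplotSummary:
    def test_linear_interpolation_quartiles(self):
        ds = make_labeled({"L1": 100})
        ds["hr_bpm"] = np.arange(1.0, 101.0)
        row = stats.level_boxplot_summary(ds).iloc[0]
        assert row["median"] == pytest.approx(50.5)
        assert row["q1"] == pytest.approx(25.75)
        assert row["q3"] == pytest.approx(75.25)
        assert row["n_outliers"] == 0

    def test_single_value_collapses_summary(self):
        ds = make_labeled({"L2": 1})
        ds["hr_bpm"] = 123.0
        row = stats.level_boxplot_summary(ds).iloc[0]
        for col in ("median", "q1", "q3", "whisker_low", "whisker_high"):
            assert row[col] == 123.0

    def test_outliers_counted_beyond_fences(self):
        ds = make_labeled({"L1": 101})
        vals = np.r_[np.linspace(100, 110, 100), 200.0]
        ds["hr_bpm"] = vals
        row = stats.level_boxplot_summary(ds).iloc[0]
        assert row["n_outliers"] == 1
        assert row["whisker_high"] <= 110.0

    def test_generated_levels_have_increasing_medians(self, labeled_small):
        summary = stats.level_boxplot_summary(labeled_small).set_index("level")
        meds = [summary.loc[l, "median"] for l in ("L1", "L2", "L3") if l in summary.index]
        assert all(a < b for a, b in zip(meds, meds[1:]))
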