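import numpy as np
import pytest
from scipy import stats as sst

from beatvar.surrogate_stats import (
    SurrogateSet,
    group_summary,
    hs_median_ci,
    make_surrogates,
    median_test_paired,
    spearman_rs,
    surr_eval_1,
    surr_eval_2,
    surr_eval_3,
)


class TestMakeSurrogates:
    def test_multiset_and_order_statistics_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        for s in make_surrogates(x, 10, seed=5):
            np.testing.assert_array_equal(np.sort(s), np.sort(x))
            assert s.mean() == pytest.approx(x.mean())
            assert s.std() == pytest.approx(x.std())

    def test_same_seed_reproduces_identical_set(self):
        x = np.arange(50.0)
        a = make_surrogates(x, 5, seed=9)
        b = make_surrogates(x, 5, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa, sb)

    def test_fifty_shuffles_of_long_series_pairwise_distinct(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(660)
        shuffles = [tuple(s) for s in make_surrogates(x, 50, seed=0)]
        assert len(set(shuffles)) == 50

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            make_surrogates(np.arange(5.0), 10, seed=0)


class TestSurrEval1:
    def test_original_at_shuffle_mean_gives_p_near_one(self):
        sh = np.concatenate([np.linspace(0.9, 1.1, 25), np.linspace(0.9, 1.1, 25)])
        res = surr_eval_1(SurrogateSet(float(sh.mean()), sh, "SampEn"))
        assert res.p_value > 0.95
        assert res.df == 49

    def test_extreme_separation_gives_tiny_p(self):
        rng = np.random.default_rng(3)
        sh = rng.normal(2.0, 0.1, 50)
        res = surr_eval_1(SurrogateSet(2.0 - 10 * 0.1, sh, "SampEn"))
        assert res.p_value < 1e-10

    def test_matches_closed_form_t_statistic(self):
        sh = np.array([1.2, 1.4, 1.1, 1.5, 1.3, 1.25, 1.35, 1.45])
        orig = 1.0
        res = surr_eval_1(SurrogateSet(orig, sh, "D_H"))
        t_hand = (sh.mean() - orig) / (sh.std(ddof=1) / np.sqrt(sh.size))
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        p_hand = 2 * sst.t.sf(abs(t_hand), sh.size - 1)
        assert res.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_zero_spread_raises(self):
        with pytest.raises(ValueError, match="spread"):
            surr_eval_1(SurrogateSet(1.0, np.full(50, 2.0), "SampEn"))


class TestMedianTestPaired:
    def test_equal_arms_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        res = median_test_paired(x, x)
        assert res.p_value == 1.0

    def test_all_positive_differences_beat_sign_test_bound(self):
        rng = np.random.default_rng(4)
        con = 1.0 + rng.uniform(0.2, 1.0, 9)
        ach = con - rng.uniform(0.1, 0.5, 9)  # strictly positive differences
        res = median_test_paired(con, ach)
        assert res.p_value <= 2 * 0.5**8  # binomial sign-test bound, n = 9
        assert res.df == 8

    def test_invariant_to_common_constant(self):
        rng = np.random.default_rng(6)
        con = rng.normal(1.5, 0.4, 9)
        ach = rng.normal(1.2, 0.4, 9)
        r1 = median_test_paired(con, ach)
        r2 = median_test_paired(con + 100.0, ach + 100.0)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-9)

    def test_ci_brackets_median_of_differences(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 0.2, 15)
        low, high = hs_median_ci(d, 0.05)
        assert low < np.median(d) < high

    def test_needs_five_pairs_and_equal_lengths(self):
        with pytest.raises(ValueError):
            median_test_paired([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            median_test_paired([1] * 6, [1] * 5)

    def test_extreme_level_interval_unbounded(self):
        d = np.arange(9.0)
        low, high = hs_median_ci(d, 1e-6)
        assert low == -np.inf and high == np.inf


class TestSurrEval23:
    def _sets(self, rng, offset=0.0, n=9):
        out = []
        for _ in range(n):
            sh = rng.normal(1.5, 0.05, 50)
            out.append(SurrogateSet(float(sh.mean()) - offset, sh, "SampEn"))
        return out

    def test_no_shuffle_effect_on_white_noise_gives_large_p(self):
        # originals indistinguishable from shuffle means
        rng = np.random.default_rng(8)
        sets = [
            SurrogateSet(float(np.mean(sh)) + rng.normal(0, 0.05), sh, "SampEn")
            for sh in (rng.normal(1.5, 0.05, 50) for _ in range(9))
        ]
        assert surr_eval_2(sets).p_value > 0.2

    def test_systematic_offset_detected(self):
        rng = np.random.default_rng(9)
        sets = self._sets(rng, offset=0.5)
        assert surr_eval_2(sets).p_value < 0.01

    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(10)
        sets = self._sets(rng)
        res = surr_eval_3(sets, sets)
        assert res.p_value == 1.0

    def test_distinct_marginals_detected(self):
        rng = np.random.default_rng(11)
        con = self._sets(rng)
        ach = [
            SurrogateSet(s.original_value, s.shuffled_values - 0.6, "SampEn")
            for s in self._sets(rng)
        ]
        assert surr_eval_3(con, ach).p_value < 0.01


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rs(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_rs(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 7.0])
        rx = sst.rankdata(x)
        ry = sst.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rs, df = spearman_rs(x, y)
        assert rs == pytest.approx(expected, abs=1e-12)
        assert df == 6

    def test_constant_vector_flagged_undefined(self):
        rs, df = spearman_rs(np.full(10, 2.0), np.arange(10.0))
        assert np.isnan(rs)
        assert df == 8


class TestGroupSummary:
    def test_two_identical_experiments_group_median_equals_either(self):
        import pandas as pd

        rows = []
        for e in ("a", "b"):
            for beat, v in enumerate([500.0, 510.0, 520.0]):
                rows.append((e, "Con", "BBI", beat, v))
        df = pd.DataFrame(rows, columns=["experiment_id", "treatment", "kind", "beat", "value"])
        per_exp, group = group_summary(df)
        assert group.loc[group["kind"] == "BBI", "Con"].iloc[0] == 510.0

    def test_percent_change_computed_between_arms(self):
        import pandas as pd

        rows = [("a", "Con", "CS", 0, 20.0), ("a", "ACh", "CS", 0, 13.0),
                ("b", "Con", "CS", 0, 22.0), ("b", "ACh", "CS", 0, 13.5)]
        df = pd.DataFrame(rows, columns=["experiment_id", "treatment", "kind", "beat", "value"])
        _, group = group_summary(df)
        row = group[group["kind"] == "CS"].iloc[0]
        assert row["pct_change"] == pytest.approx(100 * (13.25 - 21.0) / 21.0)
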