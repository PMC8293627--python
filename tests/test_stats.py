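import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import ighrep as ig
from ighrep.stats import (BinomialTestConfig, aggregate_by_group,
                          binomial_active_test, compare_groups, log2_compare,
                          normalize_frequencies)


class TestBinomialActiveTest:
    def test_zero_count_never_active(self, model):
        counts = pd.Series(0, index=model.vh_ids())
        counts.iloc[0] = 1000
        tab = binomial_active_test(counts)
        assert not tab.loc[tab["count"] == 0, "active"].any()

    def test_strong_signal_called_active(self, model):
        counts = pd.Series(10, index=model.vh_ids())
        counts.iloc[:5] = 2000
        tab = binomial_active_test(counts)
        assert tab["active"].iloc[:5].all()

    def test_uniform_null_controls_false_calls(self, model):
        # BH at 0.05 over an all-null table: few replicates show any call
        rng = np.random.default_rng(0)
        g = len(model.vh)
        any_called = 0
        reps = 100
        for _ in range(reps):
            counts = pd.Series(rng.multinomial(100_000, np.full(g, 1.0 / g)),
                               index=model.vh_ids())
            tab = binomial_active_test(counts)
            any_called += tab["active"].any()
        assert any_called / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_raw_type_one_error_rate(self, model):
        # per-gene rejection at raw alpha under the uniform null: the exact
        # test is conservative by at most one probability atom
        rng = np.random.default_rng(1)
        g = len(model.vh)
        n = 100_000
        alpha = 0.05
        rejections = []
        for _ in range(60):
            counts = rng.multinomial(n, np.full(g, 1.0 / g))
            p = sps.binom.sf(counts - 1, n, 1.0 / g)
            rejections.append(np.mean(p <= alpha))
        rate = np.mean(rejections)
        crit = int(sps.binom.isf(alpha, n, 1.0 / g))
        atom = sps.binom.pmf(crit, n, 1.0 / g)
        mc_sigma = np.std(rejections) / np.sqrt(len(rejections))
        assert alpha - atom - 3 * mc_sigma <= rate <= alpha + 3 * mc_sigma

    def test_q_values_monotone_in_p(self, model):
        rng = np.random.default_rng(2)
        counts = pd.Series(rng.integers(0, 400, len(model.vh)),
                           index=model.vh_ids())
        tab = binomial_active_test(counts).sort_values("binomial_p")
        assert (np.diff(tab["q_value"].values) >= -1e-12).all()

    def test_zero_total_raises(self, model):
        with pytest.raises(ValueError):
            binomial_active_test(pd.Series(0, index=model.vh_ids()))

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            BinomialTestConfig(alpha=1.5)


class TestNormalize:
    def test_single_gene(self):
        freq = normalize_frequencies(pd.Series({"a": 7, "b": 0}))
        assert freq["a"] == 100.0

    def test_sums_to_hundred(self):
        rng = np.random.default_rng(3)
        counts = pd.Series(rng.integers(0, 100, 50))
        assert normalize_frequencies(counts).sum() == pytest.approx(100.0)

    def test_scale_invariance(self):
        counts = pd.Series([3, 5, 9, 0, 1])
        f1 = normalize_frequencies(counts)
        f2 = normalize_frequencies(counts * 17)
        pd.testing.assert_series_equal(f1, f2)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            normalize_frequencies(pd.Series([0, 0]))


class TestLog2Compare:
    def test_identical_is_zero(self):
        means = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        out = log2_compare(means, means)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_doubling_is_one(self):
        ref = pd.Series([1.0, 4.0], index=list("ab"))
        out = log2_compare(ref * 2, ref)
        assert np.allclose(out["log2_ratio"], 1.0)

    def test_test_zero_flagged_not_minus_inf(self):
        test = pd.Series([0.0, 5.0], index=list("ab"))
        ref = pd.Series([2.0, 5.0], index=list("ab"))
        out = log2_compare(test, ref)
        assert out.loc["a", "zero_in_test"]
        assert np.isnan(out.loc["a", "log2_ratio"])

    def test_both_zero_excluded(self):
        test = pd.Series([0.0, 5.0], index=list("ab"))
        ref = pd.Series([0.0, 5.0], index=list("ab"))
        assert list(log2_compare(test, ref).index) == ["b"]

    def test_mismatched_universe_raises(self):
        with pytest.raises(ValueError):
            log2_compare(pd.Series([1.0], index=["a"]),
                         pd.Series([1.0], index=["b"]))


class TestAggregate:
    def test_one_hot_group_carries_all(self, model):
        freq = pd.Series(0.0, index=model.vh_ids())
        freq.iloc[0] = 100.0
        agg = aggregate_by_group(freq, model, "domain")
        assert agg.loc["7183/Q52", "sum"] == pytest.approx(100.0)

    def test_group_sums_partition_total(self, model):
        rng = np.random.default_rng(4)
        counts = pd.Series(rng.integers(1, 100, len(model.vh)),
                           index=model.vh_ids())
        freq = normalize_frequencies(counts)
        for axis in ("family", "clan", "state", "domain"):
            agg = aggregate_by_group(freq, model, axis)
            assert agg["sum"].sum() == pytest.approx(100.0, abs=1e-6)
            assert agg["n_genes"].sum() == len(model.vh)

    def test_proximal_domain_higher_in_knockout(self, model, wt_preset, ko_preset):
        # the knockout's 3' skew concentrates usage in the 7183/Q52 domain
        rng = np.random.default_rng(5)
        shares = {}
        for pset in (wt_preset, ko_preset):
            counts = pd.Series(rng.multinomial(20_000, pset.vh_freq),
                               index=model.vh_ids())
            agg = aggregate_by_group(normalize_frequencies(counts), model, "domain")
            shares[pset.name] = agg.loc["7183/Q52", "sum"]
        assert shares["IL7RaKO_BM"] > shares["WT_BM"]


class TestCompareGroups:
    def test_identical_groups_null(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        res = compare_groups(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(3.0, 1.0, 30)
        res = compare_groups({"a": a, "b": b})
        assert res.p_value < 0.01

    def test_anova_matches_reference(self):
        # cross-check the type-III ANOVA route against an independent
        # one-way computation on 30 random datasets
        rng = np.random.default_rng(7)
        for _ in range(30):
            groups = {f"g{i}": rng.normal(rng.normal(), 1.0, rng.integers(5, 15))
                      for i in range(3)}
            res = compare_groups(groups)
            if res.test_used != "ANOVA_typeIII":
                continue
            ref = sps.f_oneway(*groups.values())
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_kruskal_route_on_non_normal_data(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.lognormal(0, 2.0, 40) ** 2 for i in range(3)}
        res = compare_groups(groups)
        assert res.test_used == "Kruskal-Wallis"
        # independent computation of the rank statistic with tie correction
        allv = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(allv)
        n = len(allv)
        start = 0
        h = 0.0
        for v in groups.values():
            r = ranks[start:start + len(v)]
            h += r.sum() ** 2 / len(v)
            start += len(v)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(allv, return_counts=True)
        h /= 1 - ((counts ** 3 - counts).sum() / (n ** 3 - n))
        assert res.statistic == pytest.approx(h, abs=1e-8)

    def test_pairwise_bh_adjustment(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.normal(i, 1.0, 20) for i in range(4)}
        res = compare_groups(groups)
        assert len(res.pairwise) == len(list(itertools.combinations(range(4), 2)))
        p = res.pairwise["p"].values
        order = np.argsort(p)
        m = len(p)
        manual = p[order] * m / np.arange(1, m + 1)
        manual = np.minimum.accumulate(manual[::-1])[::-1]
        assert np.allclose(np.minimum(manual, 1.0), res.pairwise["q"].values[order])

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0]})
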