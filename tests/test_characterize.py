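"""Survival curves, TMB, mutation screen, group comparisons, associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from imsubtype import MutationTable, SurvivalTable
from imsubtype.characterize import (
    categorical_association,
    compare_across_subtypes,
    km_logrank,
    mutation_frequency_test,
    tmb,
)
from imsubtype.consensus import SubtypeAssignment


def _assign(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return SubtypeAssignment(labels=pd.Series(labels, index=ids,
                                              name="subtype"),
                             k=len(set(labels)))


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time_days": times, "event": events},
                                      index=pd.Index(ids, name="sample_id")))


def _muts(records):
    return MutationTable(pd.DataFrame(
        records, columns=["sample_id", "gene", "variant_class"]))


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [100.0, 200.0, 300.0, 400.0] * 2
        events = [1, 0, 1, 1] * 2
        res = km_logrank(_surv(times, events),
                         _assign(["A"] * 4 + ["B"] * 4))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_dominated_group_curve_reaches_zero(self):
        times = [40.0, 50.0, 60.0, 1000.0, 1000.0, 1000.0]
        events = [1, 1, 1, 0, 0, 0]
        res = km_logrank(_surv(times, events),
                         _assign(["A"] * 3 + ["B"] * 3))
        assert res.curves["A"]["survival"].iloc[-1] == pytest.approx(0.0)
        assert (res.curves["B"]["survival"] == 1.0).all()
        assert res.p_value < 0.05

    def test_km_without_censoring_is_empirical_survival(self):
        times = [100.0, 200.0, 300.0, 400.0, 500.0]
        res = km_logrank(
            _surv(times + [1000.0] * 3, [1] * 5 + [0] * 3),
            _assign(["A"] * 5 + ["B"] * 3))
        curve = res.curves["A"].set_index("time")["survival"]
        for i, t in enumerate(times):
            assert curve.loc[t] == pytest.approx(1.0 - (i + 1) / 5)

    def test_single_label_is_an_error(self):
        with pytest.raises(ValueError, match="two subtypes"):
            km_logrank(_surv([100.0, 200.0], [1, 1]), _assign(["A", "A"]))


class TestTMB:
    def test_counts_only_nonsilent_classes(self):
        muts = _muts([("s0", "TP53", "Missense_Mutation"),
                      ("s0", "APC", "Silent"),
                      ("s0", "KRAS", "Nonsense_Mutation")])
        with pytest.warns(UserWarning, match="absent"):
            burden = tmb(muts, ["s0", "s1"])
        assert burden["s0"] == 2.0
        assert burden["s1"] == 0.0

    def test_per_megabase_denominator(self):
        muts = _muts([("s0", f"G{i}", "Missense_Mutation") for i in range(76)])
        burden = tmb(muts, ["s0"], denominator_mb=38.0)
        assert burden["s0"] == pytest.approx(2.0)

    def test_additive_over_disjoint_partitions(self):
        rng = np.random.default_rng(0)
        records = [(f"s{rng.integers(4)}", f"G{rng.integers(20)}",
                    "Missense_Mutation") for _ in range(60)]
        samples = [f"s{i}" for i in range(4)]
        whole = tmb(_muts(records), samples)
        part = (tmb(_muts(records[:30]), samples)
                + tmb(_muts(records[30:]), samples))
        pd.testing.assert_series_equal(whole, part, check_names=False)


class TestMutationScreen:
    def test_chi_square_matches_hand_formula(self):
        # gene mutated in 10/20 of A, 0/20 of B and C
        records = [(f"a{i}", "GENE", "Missense_Mutation") for i in range(10)]
        records += [(f"a{i}", "OTHER", "Missense_Mutation") for i in range(5)]
        ids = ([f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
               + [f"c{i}" for i in range(20)])
        assign = _assign(["A"] * 20 + ["B"] * 20 + ["C"] * 20, ids=ids)
        rows = {r.gene: r for r in mutation_frequency_test(_muts(records),
                                                           assign)}
        obs = np.array([[10, 0, 0], [10, 20, 20]], dtype=float)
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        stat = ((obs - expected) ** 2 / expected).sum()
        assert rows["GENE"].chi_square_stat == pytest.approx(stat)
        assert rows["GENE"].passes_min_count

    def test_low_frequency_gene_filtered(self):
        records = [(f"a{i}", "RARE", "Missense_Mutation") for i in range(3)]
        ids = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        assign = _assign(["A"] * 10 + ["B"] * 10, ids=ids)
        rows = {r.gene: r for r in mutation_frequency_test(_muts(records),
                                                           assign)}
        assert not rows["RARE"].passes_min_count
        assert np.isnan(rows["RARE"].chi_square_p)

    def test_equal_rates_give_large_p(self):
        records = ([(f"a{i}", "G", "Missense_Mutation") for i in range(5)]
                   + [(f"b{i}", "G", "Missense_Mutation") for i in range(5)])
        ids = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
        assign = _assign(["A"] * 20 + ["B"] * 20, ids=ids)
        rows = mutation_frequency_test(_muts(records), assign)
        assert rows[0].chi_square_p > 0.9


class TestGroupComparisons:
    def test_kw_statistic_matches_hand_rank_formula(self):
        frame = pd.DataFrame(
            [[1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0]], index=["f"],
            columns=[f"s{i}" for i in range(9)])
        res = compare_across_subtypes(frame, ["f"],
                                      _assign(["A"] * 3 + ["B"] * 3
                                              + ["C"] * 3))
        # H = 7.2 uncorrected; tie correction factor 0.9 -> 8.0
        assert res[0].kruskal_wallis_stat == pytest.approx(8.0)
        assert len(res[0].pairwise) == 3

    def test_identical_groups_are_non_significant(self):
        frame = pd.DataFrame([[5.0] * 6], index=["f"],
                             columns=[f"s{i}" for i in range(6)])
        res = compare_across_subtypes(frame, ["f"],
                                      _assign(["A"] * 3 + ["B"] * 3))
        assert res[0].kruskal_wallis_p == 1.0
        assert all(p == 1.0 for p in res[0].pairwise.values())

    def test_missing_feature_skipped_with_warning(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f"],
                             columns=[f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="absent"):
            res = compare_across_subtypes(frame, ["f", "ghost"],
                                          _assign(["A"] * 2 + ["B"] * 2))
        assert [r.feature_id for r in res] == ["f"]

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(6, 30)),
                             index=[f"f{i}" for i in range(6)],
                             columns=[f"s{i}" for i in range(30)])
        assign = _assign(["A"] * 15 + ["B"] * 15,
                         ids=[f"s{i}" for i in range(30)])
        raw = compare_across_subtypes(frame, list(frame.index), assign)
        adj = compare_across_subtypes(frame, list(frame.index), assign,
                                      adjust="BH")
        for r, a in zip(raw, adj):
            assert a.kruskal_wallis_p >= r.kruskal_wallis_p - 1e-12
            assert a.adjusted


class TestCategoricalAssociation:
    def test_fisher_matches_hypergeometric_enumeration(self):
        ids = [f"s{i}" for i in range(20)]
        assign = _assign(["A"] * 10 + ["B"] * 10, ids=ids)
        factor = pd.Series(["x"] * 8 + ["y"] * 2 + ["x"] * 1 + ["y"] * 9,
                           index=ids)
        res = categorical_association(factor, assign)
        # two-sided Fisher: sum of table probabilities <= P(observed)
        rv = hypergeom(20, 9, 10)      # N, row total of "x", col total of A
        p_obs = rv.pmf(8)
        expected = sum(rv.pmf(k) for k in range(rv.support()[0],
                                                rv.support()[1] + 1)
                       if rv.pmf(k) <= p_obs + 1e-12)
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_independent_three_by_three_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        ids = [f"s{i}" for i in range(120)]
        assign = _assign(list(rng.choice(["A", "B", "C"], 120)), ids=ids)
        for _ in range(200):
            factor = pd.Series(rng.choice(["x", "y", "z"], 120), index=ids)
            pvals.append(categorical_association(factor, assign).p_value)
        assert 0.01 < np.mean(np.array(pvals) < 0.05) < 0.12

    def test_constant_factor_is_degenerate(self):
        ids = [f"s{i}" for i in range(6)]
        assign = _assign(["A"] * 3 + ["B"] * 3, ids=ids)
        with pytest.warns(UserWarning, match="degenerate"):
            res = categorical_association(pd.Series(["x"] * 6, index=ids),
                                          assign)
        assert res.p_value == 1.0

    def test_monte_carlo_close_to_asymptotic(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(90)]
        assign = _assign(list(rng.choice(["A", "B", "C"], 90)), ids=ids)
        factor = pd.Series(rng.choice(["x", "y", "z"], 90), index=ids)
        asym = categorical_association(factor, assign)
        mc = categorical_association(factor, assign, monte_carlo=True,
                                     n_permutations=2000, seed=1)
        assert abs(mc.p_value - asym.p_value) < 0.1
        mc2 = categorical_association(factor, assign, monte_carlo=True,
                                      n_permutations=2000, seed=1)
        assert mc.p_value == mc2.p_value
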