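import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cagecompare.expression_classes import (
    EnrichmentCriteria,
    call_expressed,
    enrichment_agreement,
    enrichment_call,
    expressed_agreement_per_tissue,
    min_count_for_tolerance,
    tissue_distribution,
    ubiquitous_set,
    ubiquity_agreement,
    _ttest_two_sample,
)

from conftest import make_matrix, make_sheet


def _calls(bools, genes, samples, label="A"):
    m = make_matrix(np.where(np.asarray(bools), 2.0, 0.0), genes, samples, label=label)
    return call_expressed(m, 1.0)


class TestCallExpressed:
    def test_strictly_greater_than_threshold(self):
        m = make_matrix([[1.0, 1.0001, 0.0]], ["g1"], ["s1", "s2", "s3"])
        c = call_expressed(m, 1.0)
        assert list(c.calls.loc["g1"]) == [False, True, False]

    def test_all_zero_matrix_all_false(self):
        m = make_matrix(np.zeros((3, 2)), ["g1", "g2", "g3"], ["s1", "s2"])
        assert not call_expressed(m).calls.to_numpy().any()


class TestUbiquity:
    def test_all_samples_required(self):
        n = 27
        vals = np.full((2, n), 5.0)
        vals[1, 0] = 0.5  # 26/27
        c = call_expressed(make_matrix(vals, ["gin", "gout"], [f"s{i}" for i in range(n)]))
        assert ubiquitous_set(c) == {"gin"}

    @pytest.mark.parametrize("tol,n,expected", [(0.95, 79, 75), (0.95, 27, 25), (1.0, 10, 10), (0.5, 3, 1)])
    def test_tolerance_min_count(self, tol, n, expected):
        assert min_count_for_tolerance(tol, n) == expected

    @pytest.mark.parametrize("count_b,expected", [(75, "common"), (74, "a_only")])
    def test_printed_instantiations_27_vs_79(self, count_b, expected):
        genes = ["g"]
        calls_a = _calls([[True] * 27], genes, [f"a{i}" for i in range(27)], "A")
        bvec = [i < count_b for i in range(79)]
        calls_b = _calls([bvec], genes, [f"b{i}" for i in range(79)], "B")
        res = ubiquity_agreement(calls_a, calls_b, 0.95)
        assert ("g" in res.common) == (expected == "common")
        assert ("g" in res.a_only) == (expected == "a_only")

    def test_symmetric_instantiation_79_vs_25(self):
        genes = ["g"]
        calls_a = _calls([[i < 25 for i in range(27)]], genes, [f"a{i}" for i in range(27)], "A")
        calls_b = _calls([[True] * 79], genes, [f"b{i}" for i in range(79)], "B")
        assert "g" in ubiquity_agreement(calls_a, calls_b, 0.95).common

    def test_exhaustive_count_pairs_match_direct_rule(self):
        """All (a, b) expressed-count pairs on a 4/5-sample toy vs the rule itself."""
        from _oracles import brute_ubiquity_category

        n_a, n_b, tol = 4, 5, 0.95
        pairs = list(itertools.product(range(n_a + 1), range(n_b + 1)))
        genes = [f"g{a}_{b}" for a, b in pairs]
        mat_a = [[i < a for i in range(n_a)] for a, b in pairs]
        mat_b = [[i < b for i in range(n_b)] for a, b in pairs]
        res = ubiquity_agreement(
            _calls(mat_a, genes, [f"a{i}" for i in range(n_a)], "A"),
            _calls(mat_b, genes, [f"b{i}" for i in range(n_b)], "B"),
            tol,
        )
        for (a, b), g in zip(pairs, genes):
            expected = brute_ubiquity_category(a, n_a, b, n_b, tol)
            got = (
                "common" if g in res.common
                else "a_only" if g in res.a_only
                else "b_only" if g in res.b_only
                else None
            )
            assert got == expected, f"counts ({a}/{n_a}, {b}/{n_b})"

    def test_mismatched_universe_rejected(self):
        calls_a = _calls([[True]], ["g1"], ["a1"])
        calls_b = _calls([[True]], ["g2"], ["b1"])
        with pytest.raises(ValueError, match="symmetric difference"):
            ubiquity_agreement(calls_a, calls_b)


class TestEnrichmentCall:
    def _simple(self, rows, genes, tissues, **crit):
        samples = [(f"s_{t}", t) for t in tissues]
        m = make_matrix(rows, genes, [s for s, _ in samples])
        return enrichment_call(m, make_sheet(samples), EnrichmentCriteria(**crit))

    def test_fold_is_top_over_second(self):
        res = self._simple([[70.0, 10.0, 9.0, 1.0]], ["g"], ["t1", "t2", "t3", "t4"])
        row = res.table.loc["g"]
        assert row["top_tissue"] == "t1" and row["fold"] == pytest.approx(7.0)
        assert "g" in res.qualifying(7) and "g" not in res.qualifying(7.1)

    def test_floor_rule_for_zero_background(self):
        res = self._simple([[70.0, 0.0, 0.0]], ["g"], ["t1", "t2", "t3"], floor=0.1)
        assert res.table.loc["g", "fold"] == pytest.approx(700.0)
        assert "g" in res.qualifying(10)

    def test_exact_tie_gives_no_call(self):
        res = self._simple([[5.0, 5.0, 1.0]], ["g"], ["t1", "t2", "t3"])
        assert res.table.loc["g", "tie"]
        assert res.qualifying(3) == set()

    def test_unexpressed_top_does_not_qualify(self):
        res = self._simple([[0.9, 0.05, 0.05]], ["g"], ["t1", "t2", "t3"])
        assert res.table.loc["g", "fold"] >= 3
        assert "g" not in res.qualifying(3)

    def test_replicate_aggregation_mean_vs_max(self):
        samples = [("a1", "t1"), ("a2", "t1"), ("b1", "t2")]
        m = make_matrix([[10.0, 20.0, 2.0]], ["g"], ["a1", "a2", "b1"])
        mean_res = enrichment_call(m, make_sheet(samples), EnrichmentCriteria(aggregation="mean"))
        max_res = enrichment_call(m, make_sheet(samples), EnrichmentCriteria(aggregation="max"))
        assert mean_res.table.loc["g", "top_value"] == pytest.approx(15.0)
        assert max_res.table.loc["g", "top_value"] == pytest.approx(20.0)

    def test_random_matrix_matches_direct_scan(self, rng):
        from _oracles import brute_enrichment
        from cagecompare.expression_classes import aggregate_by_tissue

        tissues = [f"t{i}" for i in range(6)]
        samples = [(f"s{i}_{r}", t) for i, t in enumerate(tissues) for r in range(2)]
        m = make_matrix(rng.random((50, len(samples))) * 20, [f"g{i}" for i in range(50)], [s for s, _ in samples])
        sheet = make_sheet(samples)
        res = enrichment_call(m, sheet, EnrichmentCriteria())
        oracle = brute_enrichment(aggregate_by_tissue(m, sheet, "mean"), 0.1, 1.0)
        for g, (top, fold, expressed) in oracle.items():
            row = res.table.loc[g]
            assert row["top_tissue"] == top
            if top is not None:
                assert row["fold"] == pytest.approx(fold)
                assert (g in res.qualifying(3)) == (expressed and fold >= 3)

    def test_cutoff_monotonicity_nested_sets(self, rng):
        tissues = [f"t{i}" for i in range(5)]
        samples = [(f"s_{t}", t) for t in tissues]
        m = make_matrix(rng.random((100, 5)) * 30, [f"g{i}" for i in range(100)], [s for s, _ in samples])
        res = enrichment_call(m, make_sheet(samples), EnrichmentCriteria())
        assert res.qualifying(10) <= res.qualifying(7) <= res.qualifying(5) <= res.qualifying(3)


class TestEnrichmentAgreement:
    def _res(self, folds, tops, label):
        """Build an EnrichmentResult-like object from per-gene (fold, top)."""
        from cagecompare.expression_classes import EnrichmentResult

        genes = list(folds)
        table = pd.DataFrame(
            {
                "top_tissue": [tops[g] for g in genes],
                "second_tissue": ["x"] * len(genes),
                "top_value": [10.0] * len(genes),
                "second_value": [1.0] * len(genes),
                "fold": [folds[g] for g in genes],
                "tie": [False] * len(genes),
            },
            index=genes,
        )
        return EnrichmentResult(table=table, criteria=EnrichmentCriteria(), dataset_label=label)

    def test_relaxed_rule_example(self):
        a = self._res({"g": 8.0}, {"g": "liver"}, "A")
        b = self._res({"g": 3.5}, {"g": "liver"}, "B")
        assert "g" in enrichment_agreement(a, b, 7, 3).common

    def test_different_top_tissue_not_common(self):
        a = self._res({"g": 8.0}, {"g": "liver"}, "A")
        b = self._res({"g": 9.0}, {"g": "kidney"}, "B")
        res = enrichment_agreement(a, b, 7, 3)
        assert "g" not in res.common and "g" in res.discordant

    def test_exhaustive_fold_cross_matches_rule_table(self):
        from _oracles import brute_enrichment_category

        folds = [2.0, 3.0, 5.0, 7.0, 10.0]
        settings = [(5, 3), (7, 3), (7, 5), (10, 5)]
        cases = [
            (fa, fb, same)
            for fa in folds
            for fb in folds
            for same in (True, False)
        ]
        genes = [f"g{i}" for i in range(len(cases))]
        fa = {g: c[0] for g, c in zip(genes, cases)}
        fb = {g: c[1] for g, c in zip(genes, cases)}
        ta = {g: "liver" for g in genes}
        tb = {g: ("liver" if c[2] else "brain") for g, c in zip(genes, cases)}
        res_a, res_b = self._res(fa, ta, "A"), self._res(fb, tb, "B")
        for x, y in settings:
            agr = enrichment_agreement(res_a, res_b, x, y)
            for g in genes:
                expected = brute_enrichment_category(ta[g], fa[g], tb[g], fb[g], x, y)
                got = (
                    "common" if g in agr.common
                    else "a_only" if g in agr.a_only
                    else "b_only" if g in agr.b_only
                    else "discordant" if g in agr.discordant
                    else None
                )
                assert got == expected, (g, fa[g], fb[g], tb[g], x, y)

    def test_relaxed_supersets_strict(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(200)]
        fa = {g: float(rng.choice([1, 2, 4, 6, 8, 12])) for g in genes}
        fb = {g: float(rng.choice([1, 2, 4, 6, 8, 12])) for g in genes}
        tops = {g: str(rng.choice(["liver", "brain"])) for g in genes}
        a, b = self._res(fa, tops, "A"), self._res(fb, tops, "B")
        strict = enrichment_agreement(a, b, 7, 7)
        relaxed = enrichment_agreement(a, b, 7, 3)
        assert strict.common <= relaxed.common

    def test_y_above_x_rejected(self):
        a = self._res({"g": 8.0}, {"g": "liver"}, "A")
        with pytest.raises(ValueError, match="y"):
            enrichment_agreement(a, a, 3, 5)


class TestTissueDistribution:
    def test_identical_groups_p_one(self):
        t, p = _ttest_two_sample([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert t == 0 and p == pytest.approx(1.0)

    def test_separated_zero_variance_groups_significant(self):
        t, p = _ttest_two_sample([0.09] * 4, [0.04] * 4)
        assert t > 0 and p < 0.05

    def test_indicator_distribution(self):
        res = tissue_distribution({"7x": ["testis"] * 10}, tissues=["testis", "brain"])
        assert res.proportions.loc["testis", "7x"] == 1.0
        assert res.proportions.loc["brain", "7x"] == 0.0

    def test_group_tests_and_flags(self):
        settings = {
            "3x": ["liver"] * 9 + ["brain"],
            "5x": ["liver"] * 9 + ["brain"],
            "5x-3x": ["liver"] * 4 + ["brain"] * 6,
            "7x-3x": ["liver"] * 4 + ["brain"] * 6,
        }
        res = tissue_distribution(
            settings, ["liver", "brain"], strict_settings=["3x", "5x"], relaxed_settings=["5x-3x", "7x-3x"]
        )
        assert res.tests.loc["liver", "p_strict_vs_relaxed"] < 0.05
        single = tissue_distribution({"3x": ["liver"], "5x": ["liver"]}, ["liver"], strict_settings=["3x"], relaxed_settings=["5x"])
        assert "omitted" in single.tests.loc["liver", "test_groups"]


class TestExpressedAgreementPerTissue:
    def test_identical_calls_full_agreement(self):
        genes = [f"g{i}" for i in range(10)]
        calls = _calls([[True, True]] * 5 + [[False, False]] * 5, genes, ["s1", "s2"])
        sheet = make_sheet([("s1", "liver"), ("s2", "liver")])
        res = expressed_agreement_per_tissue(calls, calls, sheet, sheet)
        assert res.loc["liver", "jaccard"] == 1.0 and res.loc["liver", "concordance"] == 1.0

    def test_disjoint_expressed_sets(self):
        genes = [f"g{i}" for i in range(10)]
        a = _calls([[i < 5] for i in range(10)], genes, ["s1"])
        b = _calls([[i >= 5] for i in range(10)], genes, ["s1b"])
        res = expressed_agreement_per_tissue(a, b, make_sheet([("s1", "liver")]), make_sheet([("s1b", "liver")], "B"))
        assert res.loc["liver", "jaccard"] == 0.0
        assert res.loc["liver", "concordance"] == 0.0

    def test_any_replicate_rule_and_set_algebra_oracle(self, rng):
        genes = [f"g{i}" for i in range(200)]
        va = rng.random((200, 4)) * 3
        vb = rng.random((200, 2)) * 3
        calls_a = call_expressed(make_matrix(va, genes, ["a1", "a2", "a3", "a4"]))
        calls_b = call_expressed(make_matrix(vb, genes, ["b1", "b2"]))
        sheet_a = make_sheet([("a1", "liver"), ("a2", "liver"), ("a3", "brain"), ("a4", "brain")])
        sheet_b = make_sheet([("b1", "liver"), ("b2", "brain")], "B")
        res = expressed_agreement_per_tissue(calls_a, calls_b, sheet_a, sheet_b)
        for tissue, acols, bcols in [("liver", ["a1", "a2"], ["b1"]), ("brain", ["a3", "a4"], ["b2"])]:
            ea = {g for i, g in enumerate(genes) if (va[i][[0, 1] if tissue == "liver" else [2, 3]] > 1).any()}
            eb = {g for i, g in enumerate(genes) if (vb[i][0 if tissue == "liver" else 1] > 1)}
            expected_j = len(ea & eb) / len(ea | eb)
            assert res.loc[tissue, "jaccard"] == pytest.approx(expected_j)
            assert res.loc[tissue, "expressed_both"] == len(ea & eb)

    def test_unmatched_tissue_skipped_with_warning(self):
        genes = ["g1"]
        a = _calls([[True]], genes, ["s1"])
        b = _calls([[True]], genes, ["s2"])
        with pytest.warns(UserWarning, match="only one dataset"):
            res = expressed_agreement_per_tissue(a, b, make_sheet([("s1", "liver")]), make_sheet([("s2", "brain")], "B"))
        assert len(res) == 0
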