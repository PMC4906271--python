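"""Category proportions, fold over-representation, BH and the DE filter."""

import math

import numpy as np
import pytest

from cistarget_compare import (
    AnnotationTable,
    ExpressionTable,
    GeneSet,
    bh_adjust,
    category_proportions,
    de_overlap,
    enrichment_vs_universe,
    fold_change_filter,
    fold_overrepresentation,
)

from .oracles import hypergeom_tail_enumeration

WING = "GO-35220"


def _annotation(annotated_genes, category=WING):
    return AnnotationTable({g: {category} for g in annotated_genes})


class TestCategoryProportions:
    def test_basic_proportion(self):
        gs = GeneSet("s", frozenset(f"g{i}" for i in range(10)))
        ann = _annotation(["g0", "g1"])
        count, prop = category_proportions(gs, ann, [WING])[WING]
        assert (count, prop) == (2, 0.2)

    def test_absent_category(self):
        gs = GeneSet("s", frozenset({"g1"}))
        assert category_proportions(gs, _annotation([]), [WING])[WING] == (0, 0.0)

    def test_fully_annotated(self):
        gs = GeneSet("s", frozenset({"g1", "g2"}))
        assert category_proportions(gs, _annotation(["g1", "g2"]), [WING])[WING] == (2, 1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            category_proportions(GeneSet("s", frozenset()), _annotation([]), [WING])


class TestFoldOverrepresentation:
    def test_four_fold(self):
        a = GeneSet("a", frozenset(f"a{i}" for i in range(20)))
        b = GeneSet("b", frozenset(f"b{i}" for i in range(20)))
        ann = _annotation([f"a{i}" for i in range(4)] + ["b0"])  # 20% vs 5%
        res = fold_overrepresentation(a, b, ann, WING)
        assert res.fold == pytest.approx(4.0)
        assert not res.fold_undefined
        assert 0 <= res.p_value <= 1

    def test_equal_proportions(self):
        a = GeneSet("a", frozenset({"a1", "a2"}))
        b = GeneSet("b", frozenset({"b1", "b2"}))
        res = fold_overrepresentation(a, b, _annotation(["a1", "b1"]), WING)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_in_both_flagged(self):
        a = GeneSet("a", frozenset({"a1"}))
        b = GeneSet("b", frozenset({"b1"}))
        res = fold_overrepresentation(a, b, _annotation([]), WING)
        assert res.fold_undefined and math.isnan(res.fold)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_reference_proportion_flagged_inf(self):
        a = GeneSet("a", frozenset({"a1", "a2"}))
        b = GeneSet("b", frozenset({"b1", "b2"}))
        res = fold_overrepresentation(a, b, _annotation(["a1"]), WING)
        assert res.fold_undefined and math.isinf(res.fold)
        assert 0 < res.p_value <= 1

    def test_planted_fold_recovered_at_scale(self):
        # 4-fold planted between sets of 250 via exact-count construction
        rng = np.random.default_rng(0)
        a_ids = [f"a{i}" for i in range(250)]
        b_ids = [f"b{i}" for i in range(250)]
        annotated = list(rng.choice(a_ids, size=50, replace=False)) + list(
            rng.choice(b_ids, size=13, replace=False)
        )  # 20% vs 5.2%
        res = fold_overrepresentation(
            GeneSet("a", frozenset(a_ids)), GeneSet("b", frozenset(b_ids)),
            _annotation(annotated), WING,
        )
        assert 3.5 <= res.fold <= 4.5


class TestBH:
    def test_stepup_fixture(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_not_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_empty(self):
        assert bh_adjust([]).size == 0


class TestEnrichmentVsUniverse:
    def _fixture(self):
        universe = GeneSet("u", frozenset(f"g{i}" for i in range(8)))
        gene_set = GeneSet("s", frozenset({"g0", "g1", "g2"}))
        ann = _annotation(["g0", "g1", "g3", "g4"])  # category of size 4 in universe 8
        return gene_set, ann, universe

    def test_matches_literal_enumeration(self):
        gene_set, ann, universe = self._fixture()
        res = enrichment_vs_universe(gene_set, ann, universe, [WING])[0]
        expected = hypergeom_tail_enumeration(res.count_set, 8, 4, 3)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_category_covering_universe(self):
        universe = GeneSet("u", frozenset({"g0", "g1", "g2"}))
        gene_set = GeneSet("s", frozenset({"g0"}))
        res = enrichment_vs_universe(gene_set, _annotation(["g0", "g1", "g2"]), universe, [WING])[0]
        assert res.p_value == pytest.approx(1.0)

    def test_subset_violation_rejected(self):
        gene_set = GeneSet("s", frozenset({"zzz"}))
        universe = GeneSet("u", frozenset({"g0"}))
        with pytest.raises(ValueError):
            enrichment_vs_universe(gene_set, _annotation([]), universe, [WING])

    def test_q_values_attached_and_sorted(self):
        rng = np.random.default_rng(2)
        universe_ids = [f"g{i}" for i in range(20)]
        assignments = {}
        for cat in ["c1", "c2", "c3"]:
            for g in rng.choice(universe_ids, size=8, replace=False):
                assignments.setdefault(g, set()).add(cat)
        ann = AnnotationTable(assignments)
        gene_set = GeneSet("s", frozenset(universe_ids[:6]))
        universe = GeneSet("u", frozenset(universe_ids))
        results = enrichment_vs_universe(gene_set, ann, universe, ["c1", "c2", "c3"])
        qs = [r.q_value for r in results]
        assert qs == sorted(qs)
        for r in results:
            assert r.q_value >= r.p_value - 1e-15


class TestFoldChangeFilter:
    def test_worked_rows(self):
        expr = ExpressionTable(
            {"g1": (10, 40), "g2": (10, 10), "g3": (8, 4), "g4": (3, 5)}
        )
        kept = fold_change_filter(expr, min_fold=2, pseudocount=0)
        assert kept.ids == {"g1", "g3"}  # ratios 4, 1, 2, 1.67; inclusive threshold

    def test_min_fold_one_keeps_all(self):
        expr = ExpressionTable({"g1": (5, 9), "g2": (0.1, 0.1)})
        assert len(fold_change_filter(expr, min_fold=1, pseudocount=0)) == 2

    def test_empty_table(self):
        assert len(fold_change_filter(ExpressionTable({}), 2, 1)) == 0

    def test_zero_zero_skipped_without_pseudocount(self):
        expr = ExpressionTable({"g1": (0, 0), "g2": (0, 8)})
        kept = fold_change_filter(expr, min_fold=2, pseudocount=0)
        assert kept.ids == {"g2"}

    def test_invariant_under_condition_swap(self):
        rng = np.random.default_rng(4)
        rows = {f"g{i}": (float(a), float(b))
                for i, (a, b) in enumerate(rng.uniform(0, 100, size=(200, 2)))}
        swapped = {g: (b, a) for g, (a, b) in rows.items()}
        kept = fold_change_filter(ExpressionTable(rows), 2, 1).ids
        kept_swapped = fold_change_filter(ExpressionTable(swapped), 2, 1).ids
        assert kept == kept_swapped

    def test_tsv_round_trip(self, tmp_path):
        expr = ExpressionTable({"g1": (10.5, 40.25), "g2": (3, 5)},
                               condition_names=("fore", "hind"))
        expr.to_tsv(tmp_path / "e.tsv")
        back = ExpressionTable.from_tsv(tmp_path / "e.tsv")
        assert back.rows == expr.rows
        assert back.condition_names == ("fore", "hind")


class TestDeOverlap:
    def test_basic(self):
        targets = GeneSet("t", frozenset(f"g{i}" for i in range(1, 5)))
        de = GeneSet("d", frozenset({"g2", "g9"}))
        assert de_overlap(targets, de) == (1, 0.25)

    def test_disjoint(self):
        targets = GeneSet("t", frozenset({"g1"}))
        assert de_overlap(targets, GeneSet("d", frozenset({"x"}))) == (0, 0.0)

    def test_subset(self):
        targets = GeneSet("t", frozenset({"g1", "g2"}))
        de = GeneSet("d", frozenset({"g1", "g2", "g3"}))
        assert de_overlap(targets, de) == (2, 1.0)

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            de_overlap(GeneSet("t", frozenset()), GeneSet("d", frozenset()))
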