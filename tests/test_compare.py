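"""Operon conservation, catalog overlap, paralog sets, annotation-version
transitions, and the hypergeometric enrichment statistic."""

import itertools
import math

import pytest
from scipy import stats

from tecred import (
    GeneModel,
    TagMatch,
    build_paralog_sets,
    classify_operon_conservation,
    classify_paralog_sets,
    compare_annotation_versions,
    compare_operon_catalogs,
    hypergeometric_enrichment,
)
from tecred.annotate import ExonCall
from tecred.operons import OperonModel


def _op(gene_ids, oid="op1"):
    return OperonModel(oid, list(gene_ids), [100] * (len(gene_ids) - 1),
                       "tag_supported")


class TestConservation:
    def test_exact_match(self):
        omap = {"a": {"A"}, "b": {"B"}}
        refs = {"R": ["A", "B"]}
        assert classify_operon_conservation(_op(["a", "b"]), omap, refs) == "exact"

    def test_reference_with_extra_genes_is_partial(self):
        omap = {"a": {"A"}, "b": {"B"}}
        refs = {"R": ["A", "B", "C", "D", "E"]}
        assert classify_operon_conservation(_op(["a", "b"]), omap, refs) == "partial"

    def test_unmapped_member_is_partial_when_others_hit(self):
        omap = {"a": {"A"}}
        refs = {"R": ["A"]}
        assert (
            classify_operon_conservation(_op(["a", "b"]), omap, refs) == "partial"
        )

    def test_orthologs_outside_reference_operons_is_novel_mixed(self):
        omap = {"a": {"A"}, "b": {"B"}}
        refs = {"R": ["X", "Y"]}
        assert (
            classify_operon_conservation(_op(["a", "b"]), omap, refs)
            == "novel_mixed"
        )

    def test_no_orthologs_is_novel_divergent(self):
        assert (
            classify_operon_conservation(_op(["a", "b"]), {}, {"R": ["X"]})
            == "novel_divergent"
        )

    def test_one_to_many_image_combination_can_be_exact(self):
        # one member orthologous to two reference genes of the same operon
        omap = {"a": {"A1", "A2"}, "b": {"B"}}
        refs = {"R": ["A1", "A2", "B"]}
        assert classify_operon_conservation(_op(["a", "b"]), omap, refs) == "exact"

    def test_total_single_class(self):
        omap = {"a": {"A"}, "b": {"B"}}
        refs = {"R": ["A", "B"]}
        classes = {
            classify_operon_conservation(_op(m), omap, refs)
            for m in (["a", "b"], ["a"], ["b"])
        }
        assert classes <= {"exact", "partial", "novel_mixed", "novel_divergent"}


class TestCatalogOverlap:
    def test_identical(self):
        got = compare_operon_catalogs(
            {"o": ["g1", "g2", "g3"]}, {"x": ["g1", "g2", "g3"]}
        )
        assert got == {"o": "identical"}

    def test_same_start(self):
        got = compare_operon_catalogs({"o": ["g1", "g2", "g3"]}, {"x": ["g1", "g2"]})
        assert got == {"o": "same_start"}

    def test_same_end(self):
        got = compare_operon_catalogs({"o": ["g0", "g2", "g3"]}, {"x": ["g1", "g3"]})
        assert got == {"o": "same_end"}

    def test_overlap(self):
        got = compare_operon_catalogs({"o": ["g2", "g3"]}, {"x": ["g1", "g2"]})
        assert got == {"o": "overlap"}

    def test_disjoint_is_none(self):
        got = compare_operon_catalogs({"o": ["g8", "g9"]}, {"x": ["g1", "g2"]})
        assert got == {"o": "none"}

    def test_self_comparison_is_all_identical(self):
        catalog = {"a": ["g1", "g2"], "b": ["g3", "g4", "g5"]}
        assert set(compare_operon_catalogs(catalog, catalog).values()) == {
            "identical"
        }

    def test_best_class_precedence(self):
        theirs = {"x": ["g1", "g2"], "y": ["g1", "g2", "g3"]}
        got = compare_operon_catalogs({"o": ["g1", "g2", "g3"]}, theirs)
        assert got == {"o": "identical"}


class TestParalogSets:
    GENES = [
        GeneModel("g1", "c1", "+", 1_000, 1_900),
        GeneModel("g2", "c1", "+", 10_000, 10_900),
        GeneModel("g3", "c1", "+", 20_000, 20_900),
        GeneModel("g4", "cX", "+", 5_000, 5_900),
    ]

    def _m(self, tid, start, chrom="c1"):
        return TagMatch(tid, chrom, start, start + 13, "+")

    def test_two_gene_hits_form_a_set(self):
        multi = {"t1": [self._m("t1", 1_000), self._m("t1", 10_000)]}
        (ps,) = build_paralog_sets(multi, self.GENES)
        assert ps.member_gene_ids == frozenset({"g1", "g2"})

    def test_shared_gene_merges_sets(self):
        multi = {
            "t1": [self._m("t1", 1_000), self._m("t1", 10_000)],
            "t2": [self._m("t2", 10_050), self._m("t2", 20_000)],
        }
        (ps,) = build_paralog_sets(multi, self.GENES)
        assert ps.member_gene_ids == frozenset({"g1", "g2", "g3"})
        assert ps.seed_tag_ids == frozenset({"t1", "t2"})

    def test_intergenic_locus_dropped(self):
        multi = {"t1": [self._m("t1", 1_000), self._m("t1", 500_000)]}
        assert build_paralog_sets(multi, self.GENES) == []

    def test_sets_pairwise_disjoint(self):
        multi = {
            "t1": [self._m("t1", 1_000), self._m("t1", 10_000)],
            "t2": [self._m("t2", 20_000), self._m("t2", 5_000, "cX")],
        }
        sets = build_paralog_sets(multi, self.GENES)
        assert len(sets) == 2
        a, b = (set(s.member_gene_ids) for s in sets)
        assert not a & b

    def test_classification_against_annotated_groups(self):
        sets = build_paralog_sets(
            {
                "t1": [self._m("t1", 1_000), self._m("t1", 10_000)],
                "t2": [self._m("t2", 20_000), self._m("t2", 5_000, "cX")],
            },
            self.GENES,
        )
        annotated = [{"g1", "g2"}, {"g3", "g9"}]
        classified = classify_paralog_sets(sets, annotated, self.GENES)
        by_members = {s.member_gene_ids: s for s in classified}
        exact = by_members[frozenset({"g1", "g2"})]
        assert exact.annotation_match == "exact"
        assert exact.same_chromosome is True
        assert exact.min_member_igr == 10_000 - 1_900 - 1
        cross = by_members[frozenset({"g3", "g4"})]
        assert cross.annotation_match == "partial"
        assert cross.same_chromosome is False
        assert cross.min_member_igr is None

    def test_no_annotated_overlap_is_none(self):
        sets = build_paralog_sets(
            {"t1": [self._m("t1", 1_000), self._m("t1", 10_000)]}, self.GENES
        )
        (ps,) = classify_paralog_sets(sets, [{"g7", "g8"}], self.GENES)
        assert ps.annotation_match == "none"


class TestAnnotationVersions:
    def _call(self, tid, cat, gene="gA"):
        return ExonCall(tid, "c", "+", 100, gene if cat != "novel" else None,
                        0, cat)

    def test_transition_table(self):
        calls_a = [self._call("t1", "1a"), self._call("t2", "major_mp"),
                   self._call("t3", "novel")]
        calls_b = [self._call("t1", "1a"), self._call("t2", "1a"),
                   self._call("t3", "1a"), self._call("t4", "1a")]
        transitions, summary = compare_annotation_versions(calls_a, calls_b)
        assert transitions["t1"] == ("1a", "1a")
        assert transitions["t2"] == ("major_mp", "1a")
        # an unannotated locus in the old catalog counts as absent
        assert transitions["t3"] == ("absent", "1a")
        assert transitions["t4"] == ("absent", "1a")
        assert summary[("absent", "1a")] == 2


class TestHypergeometric:
    def test_forced_full_overlap_small_universe(self):
        assert hypergeometric_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert hypergeometric_enrichment(0, 5, 5, 10) == 1.0

    def test_saturated_parameters(self):
        assert hypergeometric_enrichment(4, 4, 4, 4) == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(6, 5, 5, 10)

    def test_agrees_with_brute_force_enumeration(self):
        for N in (4, 7, 9):
            universe = range(N)
            for K in range(N + 1):
                kset = set(range(K))
                for n in range(N + 1):
                    draws = list(itertools.combinations(universe, n))
                    for k in range(min(K, n) + 1):
                        hits = sum(
                            1 for d in draws if len(kset & set(d)) >= k
                        )
                        expected = hits / len(draws)
                        got = hypergeometric_enrichment(k, K, n, N)
                        assert math.isclose(got, expected, rel_tol=1e-12)

    def test_agrees_with_scipy_survival_function(self):
        for (k, K, n, N) in [(3, 10, 8, 30), (1, 4, 4, 50), (7, 9, 12, 40)]:
            assert hypergeometric_enrichment(k, K, n, N) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-10
            )
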