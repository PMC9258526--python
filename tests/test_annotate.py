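"""Start-codon finding, ORF validation, start-site classification,
per-gene aggregation, and trans-spliced gene-set comparison."""

import pytest

from tecred import (
    GeneModel,
    TagMatch,
    aggregate_gene_calls,
    classify_exon_call,
    compare_splicing_sets,
    find_start_codon,
    validate_orf,
)
from tecred.annotate import ExonCall


def _match(start, end, strand="+", chrom="c", tid="t1"):
    return TagMatch(tid, chrom, start, end, strand)


class TestFindStartCodon:
    def test_tag_beginning_with_atg(self):
        genome = {"c": "TTTTTTTTTATGAAACCCGGG"}
        atg, dist = find_start_codon(_match(10, 23), genome)
        assert (atg, dist) == (10, 0)

    def test_downstream_atg_distance(self):
        # tag 5' end at 100, first ATG at 112
        contig = "C" * 99 + "CCCCCCCCCCCC" + "ATG" + "C" * 80
        genome = {"c": contig}
        atg, dist = find_start_codon(_match(100, 113), genome)
        assert (atg, dist) == (112, 12)

    def test_no_atg_within_scan_returns_none(self):
        genome = {"c": "C" * 500}
        assert find_start_codon(_match(10, 23), genome, max_scan=100) is None

    def test_minus_strand_scans_leftward(self):
        # transcript-orientation ATG = forward "CAT" ending at the A
        contig = "CCCCCCCCCCCATCCCCCCCCCCCCCCCCCCCC"
        genome = {"c": contig}
        atg, dist = find_start_codon(_match(7, 20, "-"), genome)
        assert dist == 20 - atg
        assert genome["c"][atg - 3 : atg] == "CAT"


class TestValidateOrf:
    def test_immediate_stop_fails(self):
        genome = {"c": "ATGTAA" + "GCA" * 40}
        assert validate_orf(1, genome, "c", "+") is False

    def test_stop_at_boundary_codon(self):
        # ATG + 24 non-stop codons + TGA
        genome = {"c": "ATG" + "GCA" * 24 + "TGA" + "GCA" * 10}
        assert validate_orf(1, genome, "c", "+", min_orf_codons=25) is False
        assert validate_orf(1, genome, "c", "+", min_orf_codons=24) is True

    def test_clean_orf_passes(self):
        genome = {"c": "ATG" + "GCA" * 30}
        assert validate_orf(1, genome, "c", "+") is True

    def test_contig_edge_fails(self):
        genome = {"c": "ATG" + "GCA" * 5}
        assert validate_orf(1, genome, "c", "+") is False

    def test_minus_strand_frame(self):
        # transcript: ATG + GCA*30 -> forward is its revcomp
        from tecred import revcomp

        transcript = "ATG" + "GCA" * 30
        genome = {"c": revcomp(transcript)}
        atg_pos = len(transcript)  # A of the ATG sits at the forward right end
        assert validate_orf(atg_pos, genome, "c", "-") is True


class TestClassifyExonCall:
    CATALOG = [
        GeneModel("gA", "c", "+", 10_000, 10_900),
        GeneModel("gB", "c", "+", 30_000, 30_900),
    ]

    @pytest.mark.parametrize(
        "offset,expected",
        [(0, "1a"), (1, "minor_mp"), (20, "minor_mp"), (21, "major_mp"),
         (3000, "major_mp"), (3001, "novel")],
    )
    def test_boundary_offsets_upstream_of_first_exon(self, offset, expected):
        atg = 10_000 - offset
        call = classify_exon_call(_match(atg, atg + 13), atg, self.CATALOG)
        assert call.category == expected

    def test_internal_exon_exact_hit_is_1b(self):
        catalog = [
            GeneModel("gA", "c", "+", 10_000, 12_000,
                      exon_starts=(10_000, 11_000))
        ]
        call = classify_exon_call(_match(11_000, 11_013), 11_000, catalog)
        assert call.category == "1b"
        assert call.matched_gene_id == "gA"

    def test_equidistant_between_two_genes_is_other(self):
        catalog = [
            GeneModel("gA", "c", "+", 9_000, 9_500),
            GeneModel("gB", "c", "+", 11_000, 11_500),
        ]
        call = classify_exon_call(_match(10_000, 10_013), 10_000, catalog)
        assert call.category == "other"

    def test_no_same_strand_gene_is_novel(self):
        catalog = [GeneModel("gA", "c", "-", 10_000, 10_900)]
        call = classify_exon_call(_match(10_000, 10_013), 10_000, catalog)
        assert call.category == "novel"

    def test_minus_strand_offsets(self):
        catalog = [GeneModel("gA", "c", "-", 10_000, 10_900)]
        # exon start (transcript orientation) is cds_end = 10_900;
        # an ATG 15 bp downstream-of-exon (inside the CDS) is minor
        call = classify_exon_call(
            _match(10_872, 10_885, "-"), 10_885, catalog
        )
        assert call.category == "minor_mp"
        assert abs(call.offset_bp) == 15

    def test_enlarging_catalog_never_demotes_a_call(self):
        base = [GeneModel("gA", "c", "+", 10_000, 10_900)]
        good_categories = {"1a", "1b", "minor_mp"}
        for offset in (0, 5, 20):
            atg = 10_000 - offset
            before = classify_exon_call(_match(atg, atg + 13), atg, base)
            assert before.category in good_categories
            extended = base + [GeneModel("gC", "c", "+", 50_000, 50_900)]
            after = classify_exon_call(_match(atg, atg + 13), atg, extended)
            assert after.category in good_categories


class TestAggregateGeneCalls:
    def _call(self, tid, gene, atg, cat):
        return ExonCall(tid, "c", "+", atg, gene, 0, cat)

    def test_both_leaders_same_end_is_hybrid_single(self):
        calls = [self._call("t1", "gA", 100, "1a"), self._call("t2", "gA", 100, "1a")]
        out = aggregate_gene_calls(calls, {"t1": "SL1", "t2": "SL2"})
        (gc,) = out
        assert gc.sl_class == "SL1/SL2"
        assert gc.multiplicity == "single_transcript"
        assert gc.distinct_five_prime_ends == 1

    def test_two_ends_composite_category(self):
        calls = [
            self._call("t1", "gA", 100, "1a"),
            self._call("t2", "gA", 500, "major_mp"),
        ]
        out = aggregate_gene_calls(calls, {"t1": "SL1", "t2": "SL1"})
        (gc,) = out
        assert gc.multiplicity == "multiple_transcripts"
        assert gc.composite_category == "1a and major misprediction"

    def test_single_sl1_1a(self):
        out = aggregate_gene_calls(
            [self._call("t1", "gA", 100, "1a")], {"t1": "SL1"}
        )
        (gc,) = out
        assert (gc.sl_class, gc.multiplicity, gc.composite_category) == (
            "SL1", "single_transcript", "1a"
        )

    def test_all_mispredicted_bucket(self):
        calls = [
            self._call("t1", "gA", 100, "minor_mp"),
            self._call("t2", "gA", 500, "major_mp"),
        ]
        (gc,) = aggregate_gene_calls(calls, {"t1": "SL1", "t2": "SL1"})
        assert gc.composite_category == "all mispredicted exons"

    def test_novel_calls_aggregate_under_synthetic_ids(self):
        calls = [ExonCall("t1", "c", "+", 999, None, None, "novel")]
        (gc,) = aggregate_gene_calls(calls, {"t1": "SL1"})
        assert gc.gene_id.startswith("novel:")


class TestCompareSplicingSets:
    OMAP = {"g1": {"o1"}, "g2": {"o2"}, "g3": {"o3"}}

    def test_set_difference(self):
        unique, unmapped = compare_splicing_sets(
            ["g1", "g2", "g3"], [{"o1"}, {"o2"}], self.OMAP
        )
        assert unique == {"g3"}
        assert unmapped == set()

    def test_fully_covered(self):
        unique, _ = compare_splicing_sets(
            ["g1", "g2"], [{"o1", "o2"}], self.OMAP
        )
        assert unique == set()

    def test_unmapped_reported_separately(self):
        unique, unmapped = compare_splicing_sets(
            ["g1", "g4"], [{"o1"}], self.OMAP
        )
        assert unmapped == {"g4"}
        assert "g4" not in unique
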