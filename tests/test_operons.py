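"""Intergenic/intercistronic distances and operon assembly."""

import pytest

from tecred import (
    GeneModel,
    build_operons,
    compute_igr,
    detect_sl1_type,
    high_confidence,
    igr_distribution_summary,
)


def _gene(gid, start, end, strand="+", chrom="c", utr3=None):
    return GeneModel(gid, chrom, strand, start, end, utr3_end=utr3)


def _chain(*lengths_and_igrs, start=1000, strand="+"):
    """Build a plus-strand gene chain from (cds_len, igr) pairs."""
    genes = []
    pos = start
    for i, (length, igr) in enumerate(lengths_and_igrs):
        genes.append(_gene(f"g{i}", pos, pos + length - 1, strand))
        pos += length + igr
    return genes


class TestComputeIgr:
    def test_adjacent_genes_igr_zero(self):
        up = _gene("u", 1, 100)
        down = _gene("d", 101, 200)
        assert compute_igr(up, down) == 0

    def test_stated_arithmetic(self):
        up = _gene("u", 1, 100)
        down = _gene("d", 281, 400)
        assert compute_igr(up, down) == 180

    def test_nested_gene_negative(self):
        up = _gene("u", 1, 1000)
        down = _gene("d", 200, 400)
        assert compute_igr(up, down) < 0

    def test_utr3_is_the_boundary_when_annotated(self):
        up = _gene("u", 1, 100, utr3=150)
        down = _gene("d", 281, 400)
        assert compute_igr(up, down) == 130

    def test_minus_strand_transcription_order(self):
        # transcription runs right-to-left: upstream gene has higher coords
        up = _gene("u", 500, 700, "-")
        down = _gene("d", 100, 300, "-")
        assert compute_igr(up, down) == 500 - 300 - 1

    def test_cross_chromosome_is_contract_violation(self):
        with pytest.raises(ValueError):
            compute_igr(_gene("u", 1, 100, chrom="c1"), _gene("d", 1, 100, chrom="c2"))


class TestBuildOperons:
    def test_sl1_head_chains_downstream_run(self):
        genes = _chain((300, 150), (300, 100), (300, 0))
        sl = {"g0": "SL1", "g1": "SL2", "g2": "SL1/SL2"}
        (op,) = build_operons(genes, sl)
        assert op.gene_ids == ["g0", "g1", "g2"]
        assert op.support == "tag_supported"
        assert op.hybrid is True
        assert op.icr_bp == [150, 100]

    def test_unknown_head_gives_predicted_run_alone(self):
        genes = _chain((300, 150), (300, 100), (300, 0))
        sl = {"g1": "SL2", "g2": "SL2"}  # g0 unknown
        (op,) = build_operons(genes, sl)
        assert op.gene_ids == ["g1", "g2"]
        assert op.support == "predicted"

    def test_include_unknown_head_flag(self):
        genes = _chain((300, 150), (300, 100), (300, 0))
        sl = {"g1": "SL2", "g2": "SL2"}
        (op,) = build_operons(genes, sl, include_unknown_head=True)
        assert op.gene_ids == ["g0", "g1", "g2"]
        assert op.support == "predicted"

    def test_opposite_strand_never_chains(self):
        genes = [_gene("g0", 1000, 1300, "+"), _gene("g1", 1500, 1800, "-")]
        assert build_operons(genes, {"g0": "SL1", "g1": "SL2"}) == []

    def test_strict_mode_requires_pure_sl1_head(self):
        genes = _chain((300, 150), (300, 100))
        sl = {"g0": "SL1/SL2", "g1": "SL2"}
        (default,) = build_operons(genes, sl)
        assert default.support == "tag_supported"
        assert default.gene_ids == ["g0", "g1"]
        (strict,) = build_operons(genes, sl, allow_hybrid_head=False)
        assert strict.support == "predicted"
        assert strict.gene_ids == ["g0", "g1"]

    def test_long_icr_warned_not_split(self):
        genes = _chain((300, 2500), (300, 0))
        sl = {"g0": "SL1", "g1": "SL2"}
        (op,) = build_operons(genes, sl)
        assert op.gene_ids == ["g0", "g1"]
        assert "icr_gt_2kb" in op.warnings

    def test_max_icr_splits_chains(self):
        genes = _chain((300, 100), (300, 4759), (300, 0))
        sl = {"g0": "SL1", "g1": "SL2", "g2": "SL2"}
        ops = build_operons(genes, sl, max_icr=2000)
        assert [o.gene_ids for o in ops] == [["g0", "g1"]]

    def test_removing_head_evidence_flips_support_only(self):
        genes = _chain((300, 150), (300, 100), (300, 80))
        sl = {"g0": "SL1", "g1": "SL2", "g2": "SL2"}
        (with_head,) = build_operons(genes, sl)
        sl_no_head = {k: v for k, v in sl.items() if k != "g0"}
        (without,) = build_operons(genes, sl_no_head)
        assert with_head.support == "tag_supported"
        assert without.support == "predicted"
        assert without.gene_ids == with_head.gene_ids[1:]

    def test_each_gene_in_at_most_one_operon(self, default_run):
        truth, result = default_run
        seen = set()
        for op in result.operons:
            for g in op.gene_ids:
                assert g not in seen
                seen.add(g)

    def test_recovered_icrs_equal_pairwise_compute_igr(self, default_sim, default_run):
        _, _, genes, _, _ = default_sim
        _, result = default_run
        by_id = {g.gene_id: g for g in genes}
        for op in result.operons:
            pairwise = [
                compute_igr(by_id[a], by_id[b])
                for a, b in zip(op.gene_ids, op.gene_ids[1:])
            ]
            assert pairwise == op.icr_bp


class TestSl1Type:
    def test_icr_zero_is_sl1_type(self):
        genes = _chain((300, 0), (300, 0))
        (op,) = detect_sl1_type(genes, {"g0": "SL1", "g1": "SL1"})
        assert op.sl1_type is True
        assert op.warnings == []

    def test_icr_one_is_potential(self):
        genes = _chain((300, 1), (300, 0))
        (op,) = detect_sl1_type(genes, {"g0": "SL1", "g1": "SL1"})
        assert "potential" in op.warnings

    def test_large_icr_is_not_sl1_type(self):
        genes = _chain((300, 500), (300, 0))
        assert detect_sl1_type(genes, {"g0": "SL1", "g1": "SL1"}) == []


class TestIgrSummary:
    def test_exclusion_and_median(self):
        genes = _chain((300, 100), (300, 250), (300, 6000), (300, 0))
        sl = {"g1": "SL1", "g2": "SL1", "g3": "SL1"}
        summary = igr_distribution_summary(genes, sl)
        assert summary["excluded_gt_exclusion"] == 1
        assert summary["classes"]["SL1"]["median"] == 175.0
        assert summary["classes"]["SL1"]["n"] == 2

    def test_all_excluded_gives_empty_summary(self):
        genes = _chain((300, 9000), (300, 0))
        summary = igr_distribution_summary(genes, {"g1": "SL1"})
        assert summary["excluded_gt_exclusion"] == 1
        assert summary["classes"] == {}

    def test_nested_pair_counts_in_negative_bin(self):
        genes = [_gene("g0", 1000, 3000), _gene("g1", 1500, 1800)]
        summary = igr_distribution_summary(genes, {"g1": "SL2"})
        assert summary["classes"]["SL2"]["histogram"]["<0"] == 1


def test_high_confidence_rule():
    from tecred import OperonModel

    ops = [
        OperonModel("a", ["g1", "g2"], [100], "tag_supported"),
        OperonModel("b", ["g3", "g4"], [100], "predicted"),
        OperonModel("c", ["g5", "g6", "g7"], [100, 100], "predicted"),
    ]
    assert [o.operon_id for o in high_confidence(ops)] == ["a", "c"]
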