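"""End-to-end pipeline: tag catalog -> genome search -> start-site
classification -> operon inference -> comparative analyses -> reports.

All analysis stages are deterministic; rerunning the same configuration on
the same inputs produces byte-identical outputs (no timestamps are written
into result files).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from . import io as tio
from .annotate import (
    DEFAULT_MAX_SCAN,
    DEFAULT_MIN_ORF_CODONS,
    MINOR_MP_MAX_OFFSET,
    NOVEL_EXON_RADIUS,
    ExonCall,
    GeneCall,
    GeneModel,
    aggregate_gene_calls,
    classify_matches,
)
from .catalog import DEFAULT_MIN_TAG_LENGTH, TagRecord, collapse_nested_tags
from .compare import (
    ParalogSet,
    build_paralog_sets,
    classify_operon_conservation,
    classify_paralog_sets,
    compare_operon_catalogs,
)
from .operons import (
    DEFAULT_IGR_EXCLUSION,
    DEFAULT_SL1_TYPE_MAX_ICR,
    OperonModel,
    build_operons,
    detect_sl1_type,
    high_confidence,
    igr_distribution_summary,
)
from .report import (
    category_table,
    catalog_overlap_table,
    conservation_table,
    gene_sl_table,
    operon_size_table,
    tag_overview_table,
    transcript_multiplicity_tables,
)
from .search import (
    DEFAULT_ACCEPTOR_WEIGHTS,
    DEFAULT_MIN_ACCEPTOR_SCORE,
    TagMatch,
    map_tags,
)

log = logging.getLogger("tecred")


@dataclass
class RunConfig:
    """All pipeline inputs and tunables, echoed into every output header."""

    tags_path: str = ""
    genome_path: str = ""
    gff3_path: str = ""
    output_dir: str = "tecred_out"
    ortholog_map_path: str | None = None
    reference_operons_path: str | None = None
    external_operons_path: str | None = None
    paralog_groups_path: str | None = None
    min_tag_length: int = DEFAULT_MIN_TAG_LENGTH
    acceptor_weights: tuple[int, ...] = DEFAULT_ACCEPTOR_WEIGHTS
    min_acceptor_score: int = DEFAULT_MIN_ACCEPTOR_SCORE
    max_scan: int = DEFAULT_MAX_SCAN
    min_orf_codons: int = DEFAULT_MIN_ORF_CODONS
    minor_max_offset: int = MINOR_MP_MAX_OFFSET
    novel_radius: int = NOVEL_EXON_RADIUS
    igr_exclusion: int = DEFAULT_IGR_EXCLUSION
    sl1_type_max_icr: int = DEFAULT_SL1_TYPE_MAX_ICR
    max_icr: int | None = None
    strict_sl1_head: bool = False
    collapse_globally: bool = False
    seed: int = 0

    def header(self) -> str:
        return "# config: " + json.dumps(asdict(self), sort_keys=True)


@dataclass
class RunResult:
    """In-memory bundle of everything the pipeline produced."""

    tags: list[TagRecord]
    matches_by_tag: dict[str, list[TagMatch]]
    status_by_tag: dict[str, str]
    calls: list[ExonCall]
    rejected: list[tuple[TagMatch, str]]
    gene_calls: list[GeneCall]
    sl_by_gene: dict[str, str]
    operons: list[OperonModel]
    sl1_type_operons: list[OperonModel]
    high_confidence_operons: list[OperonModel]
    igr_summary: dict
    paralog_sets: list[ParalogSet]
    conservation: dict[str, str] = field(default_factory=dict)
    catalog_overlap: dict[str, str] = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)


def run_pipeline(
    config: RunConfig,
    tags: list[TagRecord] | None = None,
    genome: Mapping[str, str] | None = None,
    genes: list[GeneModel] | None = None,
    write: bool = True,
) -> RunResult:
    """Execute every stage in order and (optionally) write the report bundle.

    Inputs may be passed in memory; otherwise they are loaded from the
    paths in ``config``. An empty tag table is not an error: it produces
    all-zero tables with a warning.
    """
    if tags is None:
        tags = tio.read_tags_tsv(config.tags_path)
    if genome is None:
        genome = tio.read_fasta(config.genome_path)
    if genes is None:
        genes = tio.read_gff3(config.gff3_path)
    if not tags:
        log.warning("empty tag table: all reports will be zero")

    sl_by_tag = {t.tag_id: t.sl_class for t in tags}
    by_id = {t.tag_id: t for t in tags}

    # stage: genome search
    matches_by_tag, status_by_tag = map_tags(
        tags, genome, config.acceptor_weights, config.min_acceptor_score
    )
    n_matched = sum(1 for s in status_by_tag.values() if s != "unmatched")
    _stage(stage_counts := [], "genome_search", len(tags), n_matched)

    # stage: start-site classification (unique matches only)
    unique_matches = [
        matches_by_tag[t.tag_id][0]
        for t in tags
        if status_by_tag[t.tag_id] == "unique"
    ]
    calls, rejected = classify_matches(
        unique_matches, genome, genes, config.max_scan, config.min_orf_codons,
        config.minor_max_offset, config.novel_radius,
    )
    _stage(stage_counts, "exon_annotation", len(unique_matches), len(calls))
    gene_calls = aggregate_gene_calls(calls, sl_by_tag)

    # stage: paralog discovery from multi-hit tags
    multi_ids = [tid for tid, s in status_by_tag.items() if s == "multi"]
    pool = tags if config.collapse_globally else [by_id[t] for t in multi_ids]
    loci = {
        tid: [(m.chrom, m.start, m.end, m.strand) for m in matches_by_tag[tid]]
        for tid in (t.tag_id for t in pool)
    }
    collapsed = collapse_nested_tags(pool, loci)
    multi_map = {
        t.tag_id: matches_by_tag[t.tag_id]
        for t in collapsed
        if status_by_tag[t.tag_id] == "multi"
    }
    paralog_sets = build_paralog_sets(multi_map, genes)
    if config.paralog_groups_path:
        groups = tio.read_paralog_groups_tsv(config.paralog_groups_path)
        paralog_sets = classify_paralog_sets(paralog_sets, groups, genes)
    _stage(stage_counts, "paralog_analysis", len(multi_ids), len(paralog_sets))

    # stage: operon inference
    sl_by_gene = {
        gc.gene_id: gc.sl_class
        for gc in gene_calls
        if gc.sl_class in ("SL1", "SL2", "SL1/SL2")
        and not gc.gene_id.startswith("novel:")
    }
    operons = build_operons(
        genes, sl_by_gene,
        allow_hybrid_head=not config.strict_sl1_head,
        max_icr=config.max_icr,
    )
    sl1_ops = detect_sl1_type(genes, sl_by_gene, config.sl1_type_max_icr)
    hiconf = high_confidence(operons)
    igr_summary = igr_distribution_summary(genes, sl_by_gene, config.igr_exclusion)
    _stage(stage_counts, "operon_inference", len(sl_by_gene), len(operons))

    # stage: comparative
    conservation: dict[str, str] = {}
    overlap: dict[str, str] = {}
    if config.ortholog_map_path and config.reference_operons_path:
        omap = tio.read_two_column_tsv(config.ortholog_map_path)
        ref_ops = tio.read_operon_catalog_tsv(config.reference_operons_path)
        tag_supported = [o for o in operons if o.support == "tag_supported"]
        conservation = {
            o.operon_id: classify_operon_conservation(o, omap, ref_ops)
            for o in tag_supported
        }
    if config.external_operons_path:
        ext = tio.read_operon_catalog_tsv(config.external_operons_path)
        ours = {o.operon_id: o.gene_ids for o in operons}
        overlap = compare_operon_catalogs(ours, ext)

    tables = _build_tables(
        tags, status_by_tag, sl_by_tag, calls, gene_calls, operons + sl1_ops,
        conservation, overlap,
    )

    result = RunResult(
        tags=tags,
        matches_by_tag=matches_by_tag,
        status_by_tag=status_by_tag,
        calls=calls,
        rejected=rejected,
        gene_calls=gene_calls,
        sl_by_gene=sl_by_gene,
        operons=operons,
        sl1_type_operons=sl1_ops,
        high_confidence_operons=hiconf,
        igr_summary=igr_summary,
        paralog_sets=paralog_sets,
        conservation=conservation,
        catalog_overlap=overlap,
        tables=tables,
        stage_counts=stage_counts,
    )
    if write:
        _write_bundle(config, result)
    return result


def _stage(counts: list, name: str, n_in: int, n_out: int) -> None:
    counts.append((name, n_in, n_out))
    log.info("stage %s: %d in, %d out", name, n_in, n_out)


def _build_tables(tags, status_by_tag, sl_by_tag, calls, gene_calls, operons,
                  conservation, overlap) -> dict:
    n_by_class = Counter(t.sl_class for t in tags)
    matched = Counter(
        t.sl_class for t in tags if status_by_tag[t.tag_id] != "unmatched"
    )
    uniq = Counter(t.sl_class for t in tags if status_by_tag[t.tag_id] == "unique")
    multi = Counter(t.sl_class for t in tags if status_by_tag[t.tag_id] == "multi")
    cat_by_class: dict[str, Counter] = {"SL1": Counter(), "SL2": Counter()}
    for c in calls:
        cat_by_class.setdefault(sl_by_tag.get(c.tag_id, "SL1"), Counter())[
            c.category
        ] += 1
    singles, multis = transcript_multiplicity_tables(gene_calls)
    tables = {
        "tag_overview": tag_overview_table(n_by_class, matched, uniq, multi),
        "categories": category_table(cat_by_class),
        "genes_by_sl": gene_sl_table(gene_calls),
        "single_transcript": singles,
        "multiple_transcripts": multis,
        "operon_sizes": operon_size_table(operons),
    }
    if conservation:
        tables["conservation"] = conservation_table(conservation)
    if overlap:
        tables["catalog_overlap"] = catalog_overlap_table(overlap)
    return tables


def _write_bundle(config: RunConfig, result: RunResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header()

    all_matches = [m for ms in result.matches_by_tag.values() for m in ms]
    all_matches.sort(key=lambda m: (m.chrom, m.start, m.strand, m.tag_id))
    with open(out / "matches.tsv", "w") as fh:
        fh.write(header + "\n")
    tio.write_matches_tsv(all_matches, out / "matches.tsv.tmp")
    _append_after_header(out / "matches.tsv", out / "matches.tsv.tmp")

    with open(out / "calls.tsv", "w") as fh:
        fh.write(header + "\n")
    tio.write_calls_tsv(result.calls, out / "calls.tsv.tmp")
    _append_after_header(out / "calls.tsv", out / "calls.tsv.tmp")

    tio.write_gene_calls_tsv(result.gene_calls, out / "gene_calls.tsv")
    tio.write_operons_tsv(
        result.operons + result.sl1_type_operons, out / "operons.tsv"
    )
    tio.write_novel_gff3(result.calls, out / "novel_candidates.gff3")

    with open(out / "paralog_sets.tsv", "w") as fh:
        fh.write(header + "\n")
        fh.write(
            "members\tseed_tags\tannotation_match\tsame_chromosome\tmin_member_igr\n"
        )
        for ps in result.paralog_sets:
            fh.write(
                ";".join(sorted(ps.member_gene_ids))
                + "\t" + ";".join(sorted(ps.seed_tag_ids))
                + f"\t{ps.annotation_match or ''}"
                + f"\t{'' if ps.same_chromosome is None else ps.same_chromosome}"
                + f"\t{'' if ps.min_member_igr is None else ps.min_member_igr}\n"
            )

    summary: dict = {"igr_summary": result.igr_summary}
    for name, df in result.tables.items():
        df.to_csv(out / f"table_{name}.tsv", sep="\t", index=False)
        summary[name] = df.to_dict(orient="records")
    summary["n_high_confidence_operons"] = len(result.high_confidence_operons)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=str)

    manifest = {
        "config": asdict(config),
        "stages": [
            {"stage": s, "n_in": a, "n_out": b} for s, a, b in result.stage_counts
        ],
        "outputs": sorted(
            p.name
            for p in out.iterdir()
            if not p.name.endswith(".tmp")
            and p.name not in ("manifest.json", "run.log")
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    with open(out / "run.log", "w") as fh:
        for s, a, b in result.stage_counts:
            fh.write(f"stage {s}: {a} in, {b} out\n")


def _append_after_header(target: Path, tmp: Path) -> None:
    with open(target, "a") as fh, open(tmp) as src:
        fh.write(src.read())
    tmp.unlink()
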