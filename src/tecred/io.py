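"""Readers and writers for the pipeline's on-disk formats.

Genomes travel as FASTA (read via Biopython), gene catalogs as GFF3 (read
via gffutils into :class:`~tecred.annotate.GeneModel`), and tabular
artifacts as TSV (pandas). All emitted coordinates are 1-based inclusive
except the optional BED6 export, which the writer converts to 0-based
half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .annotate import ExonCall, GeneCall, GeneModel
from .catalog import TagRecord
from .operons import OperonModel
from .search import TagMatch

FASTA_WRAP = 60


# ---------------------------------------------------------------------------
# genome


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# gene catalog (GFF3)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS (and three_prime_UTR) features, 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.cds_start)):
            lo, hi = g.cds_start, g.cds_end
            utr = ""
            if g.utr3_end is not None:
                if g.strand == "+":
                    u_lo, u_hi = hi + 1, g.utr3_end
                    hi_full = g.utr3_end
                    lo_full = lo
                else:
                    u_lo, u_hi = g.utr3_end, lo - 1
                    lo_full = g.utr3_end
                    hi_full = hi
                utr = (
                    f"{g.chrom}\ttecred_sim\tthree_prime_UTR\t{u_lo}\t{u_hi}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene_id}.t1\n"
                )
            else:
                lo_full, hi_full = lo, hi
            fh.write(
                f"{g.chrom}\ttecred_sim\tgene\t{lo_full}\t{hi_full}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
                f"{g.chrom}\ttecred_sim\tmRNA\t{lo_full}\t{hi_full}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exon_starts):
                # single-exon models: exon == CDS span
                fh.write(
                    f"{g.chrom}\ttecred_sim\texon\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i + 1};Parent={g.gene_id}.t1\n"
                )
                break
            fh.write(
                f"{g.chrom}\ttecred_sim\tCDS\t{lo}\t{hi}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )
            fh.write(utr)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via gffutils (in-memory database).

    CDS segments of each gene are merged into one span; each CDS segment's
    transcript-orientation start becomes an exon start (first entry = the
    5'-most). An annotated three_prime_UTR supplies ``utr3_end``.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            continue
        starts = [c.start for c in cds]
        ends = [c.end for c in cds]
        lo, hi = min(starts), max(ends)
        if gene.strand == "+":
            exon_starts = tuple(sorted(starts))
        else:
            exon_starts = tuple(sorted(ends, reverse=True))
        utr3 = None
        utrs = list(db.children(gene, featuretype="three_prime_UTR"))
        if utrs:
            utr3 = max(u.end for u in utrs) if gene.strand == "+" else min(
                u.start for u in utrs
            )
        models.append(
            GeneModel(gene.id, gene.seqid, gene.strand, lo, hi, exon_starts, utr3)
        )
    models.sort(key=lambda g: (g.chrom, g.cds_start))
    return models


# ---------------------------------------------------------------------------
# tabular artifacts


def write_tags_tsv(tags: Sequence[TagRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(t.tag_id, t.sequence, t.sl_class, t.observation_count) for t in tags],
        columns=["tag_id", "sequence", "sl_class", "count"],
    ).to_csv(path, sep="\t", index=False)


def read_tags_tsv(path: str | Path) -> list[TagRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "sl_class": str})
    return [
        TagRecord(str(r.tag_id), r.sequence, r.sl_class, int(r.count))
        for r in df.itertuples()
    ]


def write_matches_tsv(
    matches: Iterable[TagMatch], path: str | Path, convention_note: bool = True
) -> None:
    rows = [
        (m.tag_id, m.chrom, m.start, m.end, m.strand, m.acceptor_context,
         m.acceptor_score, m.status)
        for m in matches
    ]
    with open(path, "w") as fh:
        if convention_note:
            fh.write("# coordinates: 1-based inclusive, forward reference\n")
        pd.DataFrame(
            rows,
            columns=["tag_id", "chrom", "start", "end", "strand",
                     "acceptor_context", "acceptor_score", "status"],
        ).to_csv(fh, sep="\t", index=False)


def read_matches_tsv(path: str | Path) -> list[TagMatch]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TagMatch(str(r.tag_id), str(r.chrom), int(r.start), int(r.end),
                 r.strand, str(r.acceptor_context), int(r.acceptor_score),
                 r.status)
        for r in df.itertuples()
    ]


def write_bed6(matches: Iterable[TagMatch], path: str | Path) -> None:
    """BED6 export; the writer performs the 0-based half-open conversion."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(
                f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.tag_id}\t"
                f"{m.acceptor_score}\t{m.strand}\n"
            )


def write_calls_tsv(calls: Sequence[ExonCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive, forward reference\n")
        pd.DataFrame(
            [
                (c.tag_id, c.matched_gene_id or "", c.chrom, c.strand,
                 c.atg_position, "" if c.offset_bp is None else c.offset_bp,
                 c.category)
                for c in calls
            ],
            columns=["tag_id", "gene_id", "chrom", "strand", "atg_position",
                     "offset_bp", "category"],
        ).to_csv(fh, sep="\t", index=False)


def write_gene_calls_tsv(calls: Sequence[GeneCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.gene_id, c.sl_class, c.distinct_five_prime_ends, c.multiplicity,
             c.composite_category)
            for c in calls
        ],
        columns=["gene_id", "sl_class", "n_ends", "multiplicity",
                 "composite_category"],
    ).to_csv(path, sep="\t", index=False)


def write_operons_tsv(operons: Sequence[OperonModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            (o.operon_id, ";".join(o.gene_ids),
             ";".join(str(i) for i in o.icr_bp), o.support, o.hybrid,
             o.sl1_type, ";".join(o.warnings))
            for o in operons
        ],
        columns=["operon_id", "genes", "icrs", "support", "hybrid", "sl1_type",
                 "warnings"],
    ).to_csv(path, sep="\t", index=False)


def write_novel_gff3(calls: Sequence[ExonCall], path: str | Path,
                     tag_length: int = 14) -> None:
    """Export novel start-site candidates as GFF3 region features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.atg_position)):
            if c.category != "novel":
                continue
            if c.strand == "+":
                lo, hi = c.atg_position, c.atg_position + tag_length - 1
            else:
                lo, hi = c.atg_position - tag_length + 1, c.atg_position
            fh.write(
                f"{c.chrom}\ttecred\tregion\t{lo}\t{hi}\t.\t{c.strand}\t.\t"
                f"ID=novel_{c.tag_id};tag={c.tag_id}\n"
            )


def read_two_column_tsv(path: str | Path) -> dict[str, set[str]]:
    """Ortholog-map style TSV (query, reference); one-to-many allowed."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query", "reference"],
                     comment="#", dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.query, set()).add(r.reference)
    return out


def read_operon_catalog_tsv(path: str | Path) -> dict[str, list[str]]:
    """Operon catalog TSV: operon_id <tab> semicolon-joined ordered genes."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["operon_id", "genes"], comment="#", dtype=str)
    return {r.operon_id: r.genes.split(";") for r in df.itertuples()}


def read_paralog_groups_tsv(path: str | Path) -> list[set[str]]:
    """Annotated paralog groups: group_id <tab> semicolon-joined genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["group_id", "genes"],
                     comment="#", dtype=str)
    return [set(r.genes.split(";")) for r in df.itertuples()]
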