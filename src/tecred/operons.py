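"""Operon inference from spliced-leader classes and intercistronic distances.

In nematodes, genes inside an operon are resolved from a polycistronic
precursor by SL2 (or SL1+SL2) trans-splicing, while the first gene is SL1
spliced. Maximal runs of consecutive same-strand SL2/SL1-SL2 genes are
therefore chained into one operon; when the gene immediately upstream is a
known SL1 (or, by default, SL1/SL2) gene it heads the operon and the model
is *tag-supported*, otherwise the run alone forms a *predicted* operon.

The intergenic region (IGR) between two genes in transcription order is
the gap from the upstream gene's 3' boundary (annotated 3' UTR end, else
CDS end) to the downstream gene's CDS start; nested or overlapping genes
give negative values. The intercistronic region (ICR) is the same quantity
between consecutive operon members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotate import GeneModel

DEFAULT_IGR_EXCLUSION = 5000   # bp; genes further from their upstream
                               # neighbour are dropped from IGR summaries
DEFAULT_SL1_TYPE_MAX_ICR = 1   # bp; adjacency threshold for SL1-type operons
ICR_WARN_THRESHOLD = 2000      # bp; links longer than this are flagged
ICR_BIN = 100                  # bp histogram bin for ICRs
IGR_BIN = 500                  # bp histogram bin for IGRs

DOWNSTREAM_SL = {"SL2", "SL1/SL2"}
HEAD_SL = {"SL1", "SL1/SL2"}


@dataclass
class OperonModel:
    """An ordered run of co-transcribed genes with its intercistronic gaps."""

    operon_id: str
    gene_ids: list[str]
    icr_bp: list[int]
    support: str                     # tag_supported | predicted
    hybrid: bool = False
    sl1_type: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def compute_igr(upstream: GeneModel, downstream: GeneModel) -> int:
    """Signed intergenic distance in transcription order.

    ``downstream CDS 5' start - upstream 3' boundary - 1`` in transcript
    orientation; 0 for immediately adjacent genes, negative when the
    downstream gene nests in or overlaps the upstream one.
    """
    if upstream.chrom != downstream.chrom or upstream.strand != downstream.strand:
        raise ValueError(
            f"IGR undefined across chrom/strand: {upstream.gene_id} vs "
            f"{downstream.gene_id}"
        )
    if upstream.strand == "+":
        return downstream.cds_start - upstream.three_prime_end - 1
    return upstream.three_prime_end - downstream.cds_end - 1


def transcription_order(genes: Iterable[GeneModel]) -> dict[tuple[str, str], list[GeneModel]]:
    """Genes grouped per (chrom, strand), sorted 5'->3' in transcription order."""
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        groups.setdefault((g.chrom, g.strand), []).append(g)
    for (chrom, strand), glist in groups.items():
        glist.sort(key=lambda g: g.cds_start, reverse=(strand == "-"))
    return dict(sorted(groups.items()))


def build_operons(
    genes: Sequence[GeneModel],
    sl_by_gene: Mapping[str, str],
    allow_hybrid_head: bool = True,
    max_icr: int | None = None,
    include_unknown_head: bool = False,
) -> list[OperonModel]:
    """Chain SL2/SL1-SL2 runs into operon models.

    ``sl_by_gene`` gives the known SL class per gene (missing or
    ``unknown`` means no tag evidence). Chaining is SL-pattern driven with
    no hard distance cutoff; links with ICR > 2 kb get an ``icr_gt_2kb``
    warning, and an optional ``max_icr`` splits chains at longer links.
    ``allow_hybrid_head=False`` requires a pure-SL1 first gene for
    tag-supported models. A run with an unknown-class upstream neighbour
    is emitted alone as a predicted operon (set ``include_unknown_head``
    to pull that neighbour in).
    """
    head_classes = HEAD_SL if allow_hybrid_head else {"SL1"}
    out: list[OperonModel] = []
    counter = 0
    for (chrom, strand), ordered in transcription_order(genes).items():
        i = 0
        n = len(ordered)
        while i < n:
            if sl_by_gene.get(ordered[i].gene_id) not in DOWNSTREAM_SL:
                i += 1
                continue
            j = i
            while j + 1 < n and sl_by_gene.get(ordered[j + 1].gene_id) in DOWNSTREAM_SL:
                j += 1
            run = ordered[i : j + 1]
            members: list[GeneModel]
            if i > 0 and sl_by_gene.get(ordered[i - 1].gene_id) in head_classes:
                members = [ordered[i - 1]] + run
            elif i > 0 and include_unknown_head and ordered[i - 1].gene_id not in sl_by_gene:
                members = [ordered[i - 1]] + run
            else:
                members = run
            # tag-supported iff the first gene's SL class is known and
            # SL1-capable (SL1, or SL1/SL2 unless strict mode)
            support = (
                "tag_supported"
                if sl_by_gene.get(members[0].gene_id) in head_classes
                else "predicted"
            )
            i = j + 1
            if len(members) < 2:
                continue
            for chunk, chunk_icrs in _split_by_max_icr(members, max_icr):
                if len(chunk) < 2:
                    continue
                counter += 1
                warnings = [
                    "icr_gt_2kb" for icr in chunk_icrs if icr > ICR_WARN_THRESHOLD
                ]
                hybrid = any(
                    sl_by_gene.get(g.gene_id) == "SL1/SL2" for g in chunk
                )
                out.append(
                    OperonModel(
                        f"OP{counter:04d}",
                        [g.gene_id for g in chunk],
                        chunk_icrs,
                        support,
                        hybrid=hybrid,
                        warnings=warnings,
                    )
                )
    return out


def _split_by_max_icr(
    members: Sequence[GeneModel], max_icr: int | None
) -> list[tuple[list[GeneModel], list[int]]]:
    icrs = [compute_igr(a, b) for a, b in zip(members, members[1:])]
    if max_icr is None:
        return [(list(members), icrs)]
    chunks: list[tuple[list[GeneModel], list[int]]] = []
    cur = [members[0]]
    cur_icrs: list[int] = []
    for gene, icr in zip(members[1:], icrs):
        if icr > max_icr:
            chunks.append((cur, cur_icrs))
            cur, cur_icrs = [gene], []
        else:
            cur.append(gene)
            cur_icrs.append(icr)
    chunks.append((cur, cur_icrs))
    return chunks


def detect_sl1_type(
    genes: Sequence[GeneModel],
    sl_by_gene: Mapping[str, str],
    max_icr: int = DEFAULT_SL1_TYPE_MAX_ICR,
) -> list[OperonModel]:
    """SL1-type operons: consecutive SL1 genes with essentially no gap.

    Consecutive same-strand SL1-spliced genes separated by at most
    ``max_icr`` bp form an SL1-type operon; a 1 bp gap is only a
    *potential* SL1-type operon and is flagged accordingly.
    """
    out: list[OperonModel] = []
    counter = 0
    for (chrom, strand), ordered in transcription_order(genes).items():
        i = 0
        n = len(ordered)
        while i < n:
            if sl_by_gene.get(ordered[i].gene_id) != "SL1":
                i += 1
                continue
            j = i
            icrs: list[int] = []
            while (
                j + 1 < n
                and sl_by_gene.get(ordered[j + 1].gene_id) == "SL1"
                and compute_igr(ordered[j], ordered[j + 1]) <= max_icr
            ):
                icrs.append(compute_igr(ordered[j], ordered[j + 1]))
                j += 1
            if j > i:
                counter += 1
                warnings = ["potential"] if any(icr == 1 for icr in icrs) else []
                out.append(
                    OperonModel(
                        f"SL1OP{counter:04d}",
                        [g.gene_id for g in ordered[i : j + 1]],
                        icrs,
                        "tag_supported",
                        sl1_type=True,
                        warnings=warnings,
                    )
                )
            i = j + 1
    return out


def igr_distribution_summary(
    genes: Sequence[GeneModel],
    sl_by_gene: Mapping[str, str],
    exclusion: int = DEFAULT_IGR_EXCLUSION,
    bin_size: int = IGR_BIN,
) -> dict:
    """Per-SL-class IGR summaries to the nearest upstream neighbour.

    For every gene with a known SL class, the IGR to its nearest upstream
    same-strand neighbour is computed; values above ``exclusion`` bp are
    dropped (their count is reported). Returns per-class medians,
    quartiles and histogram counts in ``bin_size`` bp bins plus one
    negative bin for nested/overlapping pairs.
    """
    per_class: dict[str, list[int]] = {}
    excluded = 0
    for (chrom, strand), ordered in transcription_order(genes).items():
        for upstream, downstream in zip(ordered, ordered[1:]):
            sl = sl_by_gene.get(downstream.gene_id)
            if sl not in ("SL1", "SL2", "SL1/SL2"):
                continue
            igr = compute_igr(upstream, downstream)
            if igr > exclusion:
                excluded += 1
                continue
            per_class.setdefault(sl, []).append(igr)
    summary: dict = {"excluded_gt_exclusion": excluded, "classes": {}}
    for sl, values in sorted(per_class.items()):
        arr = np.asarray(values)
        hist: dict[str, int] = {}
        neg = int((arr < 0).sum())
        if neg:
            hist["<0"] = neg
        nonneg = arr[arr >= 0]
        for v in nonneg:
            lo = (int(v) // bin_size) * bin_size
            key = f"[{lo},{lo + bin_size})"
            hist[key] = hist.get(key, 0) + 1
        summary["classes"][sl] = {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "histogram": hist,
        }
    return summary


def high_confidence(operons: Sequence[OperonModel], min_predicted_genes: int = 3) -> list[OperonModel]:
    """Tag-supported operons plus predicted operons of >= 3 genes."""
    return [
        op
        for op in operons
        if op.support == "tag_supported"
        or (op.support == "predicted" and op.n_genes >= min_predicted_genes)
    ]
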