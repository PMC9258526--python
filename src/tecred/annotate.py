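"""Classification of tag-implied start sites against a gene catalog.

Each retained unique tag placement proposes a trans-splice site; the first
downstream ATG of a plausible open reading frame is the implied CDS start.
That position is compared with annotated exon starts and sorted into the
start-site categories used throughout the reports:

* ``1a`` -- coincides with an annotated first-exon (CDS) start;
* ``1b`` -- coincides with an annotated internal exon start (alternative
  5' end);
* ``minor_mp`` -- within 20 bp of the nearest annotated exon start
  (minor misprediction);
* ``major_mp`` -- further than 20 bp but with an annotated exon within
  3 kb downstream (major misprediction);
* ``novel`` -- no annotated exon within 3 kb downstream (candidate novel
  exon or gene);
* ``other`` -- ambiguous (e.g. equidistant between two genes).

Per-gene aggregation yields the SL class (SL1, SL2 or SL1/SL2 when both
leaders tag the gene) and transcript multiplicity (distinct 5' ends).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalog import revcomp
from .search import TagMatch

STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MAX_SCAN = 3000          # bp scanned downstream for the first ATG
DEFAULT_MIN_ORF_CODONS = 25      # codons that must be stop-free after the ATG
MINOR_MP_MAX_OFFSET = 20         # bp; inclusive minor/major boundary
NOVEL_EXON_RADIUS = 3000         # bp; no exon within this downstream => novel

CATEGORIES = ("1a", "1b", "minor_mp", "major_mp", "novel", "other")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: strand, CDS span, exon starts, optional 3' UTR end.

    ``exon_starts`` are the first coding positions of each exon in
    transcript orientation (forward-reference coordinates, 1-based); the
    first entry is the CDS start (``cds_start`` on plus strand,
    ``cds_end`` on minus).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...] = ()
    utr3_end: int | None = None

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.gene_id}: cds_start > cds_end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exon_starts:
            first = self.cds_start if self.strand == "+" else self.cds_end
            object.__setattr__(self, "exon_starts", (first,))

    @property
    def first_exon_start(self) -> int:
        return self.exon_starts[0]

    @property
    def three_prime_end(self) -> int:
        """3' transcript boundary: annotated UTR end, else CDS end."""
        if self.utr3_end is not None:
            return self.utr3_end
        return self.cds_end if self.strand == "+" else self.cds_start


@dataclass(frozen=True)
class ExonCall:
    """A classified tag-implied start site."""

    tag_id: str
    chrom: str
    strand: str
    atg_position: int
    matched_gene_id: str | None
    offset_bp: int | None
    category: str


@dataclass(frozen=True)
class GeneCall:
    """Per-gene aggregation of exon calls."""

    gene_id: str
    sl_class: str                       # SL1 | SL2 | SL1/SL2
    distinct_five_prime_ends: int
    category_profile: tuple[str, ...]   # sorted multiset of categories
    multiplicity: str                   # single_transcript | multiple_transcripts
    composite_category: str


def find_start_codon(
    match: TagMatch,
    genome: Mapping[str, str],
    max_scan: int = DEFAULT_MAX_SCAN,
) -> tuple[int, int] | None:
    """First ATG at or downstream of the tag's 5' end (transcript orientation).

    Returns ``(atg_position, distance)`` where ``atg_position`` is the
    forward-reference coordinate of the A (plus strand) / the base pairing
    with the A (minus strand) and ``distance`` counts bases between the
    tag 5' end and the ATG (0 when the tag begins with ATG). ``None`` if
    no ATG lies within ``max_scan`` bases.
    """
    contig = genome[match.chrom].upper()
    if match.strand == "+":
        start0 = match.start - 1
        window = contig[start0 : start0 + max_scan + 3]
        idx = window.find("ATG")
        if idx == -1 or idx > max_scan:
            return None
        return match.start + idx, idx
    # minus strand: transcript runs right-to-left on the forward reference
    end0 = match.end  # exclusive on forward axis
    lo = max(0, end0 - max_scan - 3)
    window = revcomp(contig[lo:end0])
    idx = window.find("ATG")
    if idx == -1 or idx > max_scan:
        return None
    return match.end - idx, idx


def validate_orf(
    atg_position: int,
    genome: Mapping[str, str],
    chrom: str,
    strand: str,
    min_orf_codons: int = DEFAULT_MIN_ORF_CODONS,
) -> bool:
    """True iff no in-frame stop occurs within ``min_orf_codons`` codons
    after the ATG (frame anchored at the ATG, transcript orientation).

    Returns False when the contig ends before the window can be checked.
    """
    contig = genome[chrom].upper()
    need = 3 * (min_orf_codons + 1)  # ATG + the codons to check
    if strand == "+":
        seq = contig[atg_position - 1 : atg_position - 1 + need]
    else:
        lo = atg_position - need
        if lo < 0:
            return False
        seq = revcomp(contig[lo:atg_position])
    if len(seq) < need:
        return False
    for i in range(3, need, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return False
    return True


def _downstream_distance(atg: int, exon_start: int, strand: str) -> int:
    """Signed offset from the ATG to an exon start in transcript
    orientation; positive when the exon lies downstream of the ATG."""
    return exon_start - atg if strand == "+" else atg - exon_start


def classify_exon_call(
    match: TagMatch,
    atg_position: int,
    genes: Sequence[GeneModel],
    minor_max: int = MINOR_MP_MAX_OFFSET,
    novel_radius: int = NOVEL_EXON_RADIUS,
) -> ExonCall:
    """Classify one tag-implied ATG against same-strand annotated exons.

    The offset is computed to the nearest same-strand exon start; exact
    hits on a first/internal exon give 1a/1b, offsets of 1-20 bp give a
    minor misprediction, larger offsets with an exon within
    ``novel_radius`` bp downstream give a major misprediction, and calls
    with no exon in that downstream window are novel. An ATG exactly
    equidistant from the exons of two different genes is ambiguous
    (``other``).
    """
    chrom, strand = match.chrom, match.strand
    nearest: list[tuple[int, GeneModel, int, bool]] = []  # |off|, gene, off, is_first
    best_abs: int | None = None
    downstream: list[tuple[int, GeneModel, int]] = []
    for gene in genes:
        if gene.chrom != chrom or gene.strand != strand:
            continue
        for i, ex in enumerate(gene.exon_starts):
            off = _downstream_distance(atg_position, ex, strand)
            if 0 < off <= novel_radius:
                downstream.append((off, gene, i))
            a = abs(off)
            if best_abs is None or a < best_abs:
                best_abs = a
                nearest = [(a, gene, off, i == 0)]
            elif a == best_abs:
                nearest.append((a, gene, off, i == 0))

    def call(gene_id, off, cat):
        return ExonCall(match.tag_id, chrom, strand, atg_position, gene_id, off, cat)

    if best_abs is None:  # no same-strand gene at all
        return call(None, None, "novel")
    tied_genes = {g.gene_id for _, g, _, _ in nearest}
    if len(tied_genes) > 1:
        return call(None, nearest[0][2], "other")
    _, gene, off, is_first = nearest[0]
    if best_abs == 0:
        return call(gene.gene_id, 0, "1a" if is_first else "1b")
    if best_abs <= minor_max:
        return call(gene.gene_id, off, "minor_mp")
    if downstream:
        d_off, d_gene, _ = min(downstream, key=lambda t: t[0])
        return call(d_gene.gene_id, d_off, "major_mp")
    return call(None, off, "novel")


def classify_matches(
    matches: Iterable[TagMatch],
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    max_scan: int = DEFAULT_MAX_SCAN,
    min_orf_codons: int = DEFAULT_MIN_ORF_CODONS,
    minor_max: int = MINOR_MP_MAX_OFFSET,
    novel_radius: int = NOVEL_EXON_RADIUS,
) -> tuple[list[ExonCall], list[tuple[TagMatch, str]]]:
    """Full per-match classification: ATG scan, ORF check, categorisation.

    Returns (calls, rejected) where rejected pairs each dropped match
    with a reason (``no_atg`` or ``no_orf``).
    """
    calls: list[ExonCall] = []
    rejected: list[tuple[TagMatch, str]] = []
    for m in matches:
        hit = find_start_codon(m, genome, max_scan)
        if hit is None:
            rejected.append((m, "no_atg"))
            continue
        atg, _dist = hit
        if not validate_orf(atg, genome, m.chrom, m.strand, min_orf_codons):
            rejected.append((m, "no_orf"))
            continue
        calls.append(
            classify_exon_call(m, atg, genes, minor_max, novel_radius)
        )
    return calls, rejected


_COMPOSITE_LABELS = {
    frozenset({"1a", "1b"}): "1a and 1b",
    frozenset({"1b"}): "1b",
    frozenset({"1a", "minor_mp"}): "1a and minor misprediction",
    frozenset({"1a", "major_mp"}): "1a and major misprediction",
}


def _composite_category(categories: set[str]) -> str:
    key = frozenset(categories)
    if key in _COMPOSITE_LABELS:
        return _COMPOSITE_LABELS[key]
    if categories and categories <= {"minor_mp", "major_mp"}:
        return "all mispredicted exons"
    return "others"


def novel_locus_id(call: ExonCall) -> str:
    """Synthetic gene ID under which novel calls aggregate."""
    return f"novel:{call.chrom}:{call.atg_position}:{call.strand}"


def aggregate_gene_calls(
    calls: Sequence[ExonCall],
    sl_by_tag: Mapping[str, str],
) -> list[GeneCall]:
    """Aggregate classified calls per gene into SL class and multiplicity.

    SL class is the union rule: SL1-only, SL2-only, or SL1/SL2 when both
    leaders tag the gene. Distinct 5' ends are exact-position distinct
    ATG positions. Genes with >= 2 ends are multiple-transcript and carry
    a composite category label; single-end genes carry their category.
    """
    by_gene: dict[str, list[ExonCall]] = defaultdict(list)
    for c in calls:
        gid = c.matched_gene_id if c.matched_gene_id else novel_locus_id(c)
        by_gene[gid].append(c)
    out: list[GeneCall] = []
    for gid in sorted(by_gene):
        group = by_gene[gid]
        sls = {sl_by_tag[c.tag_id] for c in group if c.tag_id in sl_by_tag}
        if sls == {"SL1"}:
            sl = "SL1"
        elif sls == {"SL2"}:
            sl = "SL2"
        elif sls >= {"SL1", "SL2"}:
            sl = "SL1/SL2"
        else:
            sl = "unknown"
        ends = len({c.atg_position for c in group})
        cats = sorted(c.category for c in group)
        if ends >= 2:
            mult = "multiple_transcripts"
            comp = _composite_category(set(cats))
        else:
            mult = "single_transcript"
            comp = cats[0]
        out.append(GeneCall(gid, sl, ends, tuple(cats), mult, comp))
    return out


def compare_splicing_sets(
    our_genes: Iterable[str],
    reference_sets: Sequence[set[str]],
    ortholog_map: Mapping[str, set[str]],
) -> tuple[set[str], set[str]]:
    """Genes trans-spliced here whose orthologs appear in no reference set.

    Returns ``(unique, unmapped)``: genes with an ortholog mapping none of
    whose images occur in any reference set, and genes lacking a mapping
    (reported separately, never counted as unique).
    """
    unique: set[str] = set()
    unmapped: set[str] = set()
    ref_union: set[str] = set().union(*reference_sets) if reference_sets else set()
    for g in our_genes:
        images = ortholog_map.get(g)
        if not images:
            unmapped.add(g)
        elif not (images & ref_union):
            unique.add(g)
    return unique, unmapped
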