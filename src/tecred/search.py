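"""Exact placement of 5' tags on a genome and splice-acceptor scoring.

Tags are mapped with no mismatches on both strands. For each placement the
7 bases immediately upstream (transcript orientation) are extracted and
scored against the nematode trans-splice acceptor consensus ``TTTTCAG``
with a position weight table that prioritises the invariant AG dinucleotide.
Tags with several equally well supported placements are routed to paralog
analysis; weaker placements are discarded.

All genomic coordinates are 1-based inclusive on the forward reference
(GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .catalog import TagRecord, revcomp

ACCEPTOR_CONSENSUS = "TTTTCAG"

#: Per-position weights over the 7-mer acceptor context. The terminal AG
#: (positions 6-7) is invariant in trans-splice acceptors and carries the
#: top weight; the preceding C is next; the T-tract is weakly weighted.
DEFAULT_ACCEPTOR_WEIGHTS = (1, 1, 1, 1, 2, 3, 3)

#: Minimum acceptor score for a placement to count as splice-supported.
DEFAULT_MIN_ACCEPTOR_SCORE = 6

MAX_ACCEPTOR_SCORE = sum(DEFAULT_ACCEPTOR_WEIGHTS)


@dataclass(frozen=True)
class TagMatch:
    """One genomic placement of a tag.

    ``start``/``end`` are 1-based inclusive forward-reference coordinates;
    for a minus-strand placement the tag's 5' end is ``end``.
    """

    tag_id: str
    chrom: str
    start: int
    end: int
    strand: str
    acceptor_context: str = ""
    acceptor_score: int = 0
    status: str = "candidate"
    reject_reason: str | None = None

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


def find_tag_matches(tag: TagRecord, genome: Mapping[str, str]) -> list[TagMatch]:
    """Every exact occurrence of ``tag.sequence`` on either strand.

    Reverse-complement occurrences are reported with strand ``-`` and
    forward-reference coordinates. Overlapping occurrences are all
    reported. Order is (chrom, start, strand).
    """
    seq = tag.sequence.upper()
    rc = revcomp(seq)
    n = len(seq)
    out: list[TagMatch] = []
    for chrom in sorted(genome):
        contig = genome[chrom].upper()
        for query, strand in ((seq, "+"), (rc, "-")):
            pos = contig.find(query)
            while pos != -1:
                out.append(
                    TagMatch(tag.tag_id, chrom, pos + 1, pos + n, strand)
                )
                pos = contig.find(query, pos + 1)
    out.sort(key=lambda m: (m.chrom, m.start, m.strand))
    return out


def extract_acceptor_context(match: TagMatch, genome: Mapping[str, str]) -> TagMatch:
    """Attach the 7-mer immediately upstream of the tag's 5' end.

    Plus strand: forward bases ``[start-7, start-1]``. Minus strand: the
    reverse complement of forward bases ``[end+1, end+7]``. A placement
    with fewer than 7 upstream bases on the contig is rejected with
    reason ``contig_edge``.
    """
    contig = genome[match.chrom]
    if match.strand == "+":
        lo = match.start - 8  # 0-based index of first context base
        if lo < 0:
            return replace(match, status="rejected", reject_reason="contig_edge")
        context = contig[lo : lo + 7].upper()
    else:
        if match.end + 7 > len(contig):
            return replace(match, status="rejected", reject_reason="contig_edge")
        context = revcomp(contig[match.end : match.end + 7].upper())
    return replace(match, acceptor_context=context)


def score_acceptor(
    context: str, weights: Sequence[int] = DEFAULT_ACCEPTOR_WEIGHTS
) -> int:
    """Weighted match count of a 7-mer against the ``TTTTCAG`` consensus."""
    if len(context) != len(ACCEPTOR_CONSENSUS):
        raise ValueError(
            f"acceptor context must be {len(ACCEPTOR_CONSENSUS)} bases, "
            f"got {context!r}"
        )
    context = context.upper()
    if any(b not in "ACGT" for b in context):
        raise ValueError(f"acceptor context has non-ACGT base: {context!r}")
    return sum(
        w for w, b, c in zip(weights, context, ACCEPTOR_CONSENSUS) if b == c
    )


def score_match(
    match: TagMatch,
    genome: Mapping[str, str],
    weights: Sequence[int] = DEFAULT_ACCEPTOR_WEIGHTS,
) -> TagMatch:
    """Extract and score the acceptor context of one placement."""
    match = extract_acceptor_context(match, genome)
    if match.status == "rejected":
        return match
    return replace(match, acceptor_score=score_acceptor(match.acceptor_context, weights))


def resolve_multimatches(
    matches: Iterable[TagMatch],
    min_score: int = DEFAULT_MIN_ACCEPTOR_SCORE,
) -> tuple[list[TagMatch], str]:
    """Apply the acceptor gate, then keep only top-scoring placements.

    Placements scoring below ``min_score`` are rejected
    (``weak_acceptor``); among the survivors only those attaining the
    maximum acceptor score are retained. One survivor -> ``unique``;
    several -> ``multi`` (candidate paralogs); none -> ``unmatched``.
    """
    matches = list(matches)
    viable = [m for m in matches if m.status != "rejected"]
    gated = []
    for m in viable:
        if m.acceptor_score < min_score:
            gated.append(replace(m, status="rejected", reject_reason="weak_acceptor"))
        else:
            gated.append(m)
    passing = [m for m in gated if m.status != "rejected"]
    if not passing:
        return [], "unmatched"
    best = max(m.acceptor_score for m in passing)
    kept = [m for m in passing if m.acceptor_score == best]
    status = "unique" if len(kept) == 1 else "multi"
    kept = [replace(m, status=status) for m in kept]
    return kept, status


def map_tags(
    tags: Iterable[TagRecord],
    genome: Mapping[str, str],
    weights: Sequence[int] = DEFAULT_ACCEPTOR_WEIGHTS,
    min_score: int = DEFAULT_MIN_ACCEPTOR_SCORE,
) -> tuple[dict[str, list[TagMatch]], dict[str, str]]:
    """Map a tag catalog: retained placements and per-tag status.

    Returns ``(matches_by_tag, status_by_tag)`` where status is one of
    ``unique``, ``multi`` or ``unmatched``.
    """
    by_tag: dict[str, list[TagMatch]] = {}
    status: dict[str, str] = {}
    for tag in tags:
        raw = find_tag_matches(tag, genome)
        scored = [score_match(m, genome, weights) for m in raw]
        kept, st = resolve_multimatches(scored, min_score)
        by_tag[tag.tag_id] = kept
        status[tag.tag_id] = st
    return by_tag, status
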