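"""Tag catalog: deduplication of raw 5' tag observations and collapsing of
nested (redundant) tag sequences.

A tag is a short (~14 nt) sequence excised just downstream of the SL
trans-splice junction; identical sequences observed repeatedly under the
same SL class collapse to one record carrying an observation count. The
same sequence under SL1 and under SL2 are distinct records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SL_CLASSES = ("SL1", "SL2")

DEFAULT_MIN_TAG_LENGTH = 10


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TagRecord:
    """A deduplicated 5' tag: sequence, SL class and observation count."""

    tag_id: str
    sequence: str
    sl_class: str
    observation_count: int = 1

    def __post_init__(self) -> None:
        if self.sl_class not in SL_CLASSES:
            raise ValueError(f"sl_class must be one of {SL_CLASSES}, got {self.sl_class!r}")
        if self.observation_count < 1:
            raise ValueError("observation_count must be >= 1")


def dedupe_tags(
    observations: Iterable[tuple[str, str]],
    min_length: int = DEFAULT_MIN_TAG_LENGTH,
) -> list[TagRecord]:
    """Collapse raw (sequence, sl_class) observations into unique records.

    One record per distinct (sequence, sl_class) pair with its
    multiplicity; output is sorted by sequence then SL class so input
    order never matters. Tag IDs are zero-padded ordinals in that order.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for row, (seq, sl) in enumerate(observations):
        seq = seq.upper()
        if any(b not in "ACGT" for b in seq):
            raise ValueError(f"row {row}: non-ACGT base in tag sequence {seq!r}")
        if len(seq) < min_length:
            raise ValueError(
                f"row {row}: tag {seq!r} shorter than minimum length {min_length}"
            )
        if sl not in SL_CLASSES:
            raise ValueError(f"row {row}: unknown SL class {sl!r}")
        counts[(seq, sl)] += 1
    keys = sorted(counts)
    width = max(4, len(str(len(keys))))
    return [
        TagRecord(f"tag{str(i + 1).zfill(width)}", seq, sl, counts[(seq, sl)])
        for i, (seq, sl) in enumerate(keys)
    ]


def _loci_contained(
    short_loci: Sequence[tuple[str, int, int, str]],
    long_loci: Sequence[tuple[str, int, int, str]],
) -> bool:
    """True if every locus of the shorter tag falls within a locus of the
    longer tag (same chrom/strand, interval containment)."""
    for chrom, start, end, strand in short_loci:
        if not any(
            chrom == c and strand == s and start >= a and end <= b
            for c, a, b, s in long_loci
        ):
            return False
    return True


def collapse_nested_tags(
    tags: Sequence[TagRecord],
    loci: Mapping[str, Sequence[tuple[str, int, int, str]]],
) -> list[TagRecord]:
    """Drop tags that are redundant substrings of a longer tag.

    A tag is dropped when its sequence is a substring of another retained
    tag of the same SL class and every one of its match loci lies within
    a locus of the longer tag (the two tag the same transcript ends).
    Length ties keep the lexicographically smaller sequence. Pure filter:
    non-overlapping tags pass through; idempotent.

    ``loci`` maps tag_id to (chrom, start, end, strand) placements.
    """
    order = sorted(tags, key=lambda t: (-len(t.sequence), t.sequence, t.sl_class))
    kept: list[TagRecord] = []
    for tag in order:
        redundant = False
        for longer in kept:
            if tag.sl_class != longer.sl_class:
                continue
            if tag.sequence == longer.sequence:
                continue
            if tag.sequence in longer.sequence and _loci_contained(
                loci.get(tag.tag_id, ()), loci.get(longer.tag_id, ())
            ):
                redundant = True
                break
        if not redundant:
            kept.append(tag)
    kept.sort(key=lambda t: (t.sequence, t.sl_class))
    return kept
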