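"""Synthetic genome, gene-catalog and 5' tag generator with ground truth.

The generator emulates the statistical structure the tag analysis assumes:
a multi-chromosome genome carrying single genes, operons with configured
SL patterns and intercistronic distances, duplicated (paralogous) loci,
and short 5' tags sampled at annotated starts, at offset starts (minor:
10-20 bp, major: > 20 bp), at intergenic sites far from any annotation,
and as unmappable sequences. Every emitted tag carries exactly one origin
label in the truth manifest, so downstream classifications can be checked
against construction.

Construction notes
------------------
* Coding-sequence filler is drawn from {A,C,G} only: with no T outside the
  planted start codons and acceptor 7-mers, no stop codon can arise in any
  reading frame, so every planted ATG trivially passes the open-reading-
  frame check regardless of frame.
* Acceptor 7-mers are stamped immediately upstream of each CDS start after
  the locus is laid out; an intercistronic gap shorter than 7 bp (SL1-type
  operons) therefore overwrites the tail of the upstream CDS, mirroring a
  trans-splice acceptor sitting at the gene junction. No analysis stage
  inspects upstream terminal stops, so this is invisible downstream.
* Planted tag sequences are kept distinct at planning time (re-drawn on
  prefix collision, paralog seeds excepted), and accidental background
  copies are broken afterwards by a deterministic single-base edit outside
  all planted loci.

Coordinates are 1-based inclusive (GFF3 convention) in the emitted catalog
and truth manifest; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .annotate import GeneModel
from .catalog import TagRecord, dedupe_tags, revcomp

ACCEPTOR = "TTTTCAG"
ORIGINS = (
    "annotated_start",
    "minor_offset",
    "major_offset",
    "novel_site",
    "unmappable",
    "paralog_seed",
)

_FILLER_ALPHABET = np.array(list("ACG"))
_BASES = np.array(list("ACGT"))


class SimSizingError(ValueError):
    """A configured layout does not fit on its chromosome."""


class SimGenerationError(RuntimeError):
    """A requested tag fraction or structure cannot be realised."""


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    Defaults describe the reference desk-scale study: 3 chromosomes of
    50 kb carrying 60 genes in total -- 27 single genes, 10 operons of 2-4
    genes (27 genes) with mixed SL patterns and intercistronic distances
    of 50-500 bp, and 3 paralog pairs -- with noiseless 14 nt tags at
    annotated starts and perfect acceptors.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 50_000
    n_single_genes: int = 27
    operon_specs: list[tuple[list[str], list[int]]] = field(
        default_factory=lambda: [
            (["SL1", "SL2"], [150]),
            (["SL1", "SL2", "SL2"], [100, 250]),
            (["SL1", "SL1/SL2"], [75]),
            (["SL1", "SL2", "SL1/SL2", "SL2"], [50, 300, 500]),
            (["SL1", "SL2"], [400]),
            (["SL1", "SL1/SL2", "SL2"], [120, 60]),
            (["SL1", "SL2", "SL2", "SL1/SL2"], [200, 90, 350]),
            (["SL1", "SL2"], [500]),
            (["SL1", "SL2", "SL1/SL2"], [80, 450]),
            (["SL1", "SL1/SL2"], [260]),
        ]
    )
    n_paralog_pairs: int = 3
    tag_length: int = 14
    fraction_at_annotated_start: float = 1.0
    fraction_minor_offset: float = 0.0
    fraction_major_offset: float = 0.0
    fraction_novel_site: float = 0.0
    fraction_unmappable: float = 0.0
    acceptor_mode: str = "perfect"          # perfect | degraded
    background_gc: float = 0.36             # nematode-like AT-rich background
    cds_length: int = 300
    base_gap: int = 1500
    minor_offset_range: tuple[int, int] = (10, 20)
    major_offset_range: tuple[int, int] = (25, 1200)
    paralog_gap: int = 3000
    count_geometric_p: float = 0.5
    margin: int = 200

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("tag fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"tag fractions must sum to 1, got {sum(fr)}")
        if self.tag_length < 10:
            raise ValueError("tag_length must be >= 10")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must lie in [0, 1]")
        if self.acceptor_mode not in ("perfect", "degraded"):
            raise ValueError(f"unknown acceptor_mode {self.acceptor_mode!r}")
        if self.cds_length < self.tag_length + 30 + 3 * 26:
            raise ValueError("cds_length too short for planted offsets and ORFs")
        for patterns, icrs in self.operon_specs:
            if len(icrs) != len(patterns) - 1:
                raise ValueError(
                    f"operon spec {patterns} needs {len(patterns) - 1} ICRs, "
                    f"got {len(icrs)}"
                )
            if any(icr < 0 for icr in icrs):
                raise ValueError("configured ICRs must be non-negative")
            bad = [p for p in patterns if p not in ("SL1", "SL2", "SL1/SL2", "unknown")]
            if bad:
                raise ValueError(f"unknown SL pattern entries {bad}")

    @property
    def fractions(self) -> tuple[float, float, float, float, float]:
        return (
            self.fraction_at_annotated_start,
            self.fraction_minor_offset,
            self.fraction_major_offset,
            self.fraction_novel_site,
            self.fraction_unmappable,
        )


@dataclass
class TruthTag:
    """Planned tag with its single origin label."""

    sequence: str
    sl_class: str               # SL1 | SL2 (label on the emitted record)
    origin: str                 # one of ORIGINS
    offset: int                 # bp; 0 except minor/major offsets
    gene_id: str | None
    chrom: str | None
    start: int | None           # 1-based 5' end (forward coords)
    strand: str | None


@dataclass
class TruthGene:
    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    exon_starts: list[int]
    utr3_end: int | None
    sl_class: str               # SL1 | SL2 | SL1/SL2 | unknown
    origin: str                 # tag origin planted for this gene


@dataclass
class GroundTruth:
    """Everything the generator knows about what it emitted."""

    genes: list[TruthGene]
    operons: list[dict]         # operon_id, gene_ids, icrs, sl_pattern
    paralog_sets: list[dict]    # gene_ids, sequence
    tags: list[TruthTag]
    config: dict

    def to_json(self) -> str:
        payload = {
            "genes": [asdict(g) for g in self.genes],
            "operons": self.operons,
            "paralog_sets": self.paralog_sets,
            "tags": [asdict(t) for t in self.tags],
            "config": self.config,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# planning helpers


def _filler(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_FILLER_ALPHABET, size=n))


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _claim(used: set[str], seq: str) -> bool:
    """Register a tag sequence; False if it (or its revcomp) is taken."""
    rc = revcomp(seq)
    if seq in used or rc in used:
        return False
    used.add(seq)
    return True


def _make_cds(rng: np.random.Generator, length: int, tag_len: int,
              used: set[str]) -> str:
    """ATG + stop-free filler + TAA with a globally unique tag prefix."""
    for _ in range(100):
        cds = "ATG" + _filler(rng, length - 6) + "TAA"
        if _claim(used, cds[:tag_len]):
            return cds
    raise SimGenerationError("could not draw a unique CDS tag prefix")


def _embed_minor(rng: np.random.Generator, cds: str, d: int, tag_len: int,
                 used: set[str]) -> str:
    """Plant an acceptor + ATG cassette inside a CDS at offset ``d``."""
    for _ in range(100):
        cassette = ACCEPTOR + "ATG" + str(rng.choice(np.array(list("CG"))))
        out = cds[: d - 7] + cassette + cds[d - 7 + len(cassette):]
        if _claim(used, out[d : d + tag_len]):
            return out
        # vary the downstream filler and retry
        tail = _filler(rng, len(cds) - (d + 4) - 3)
        cds = cds[: d + 4] + tail + "TAA"
    raise SimGenerationError("could not draw a unique minor-offset tag")


def _make_body(rng: np.random.Generator, n: int, tag_len: int,
               used: set[str]) -> str:
    """ATG + {C,G} + stop-free filler; unique tag prefix (cassette body)."""
    for _ in range(100):
        body = "ATG" + str(rng.choice(np.array(list("CG")))) + _filler(rng, n - 4)
        if _claim(used, body[:tag_len]):
            return body
    raise SimGenerationError("could not draw a unique cassette tag prefix")


def _degrade(rng: np.random.Generator, acceptor: str) -> str:
    """Mutate one non-AG consensus position (positions 1-5)."""
    pos = int(rng.integers(0, 5))
    alternatives = [b for b in "ACGT" if b != acceptor[pos]]
    base = alternatives[int(rng.integers(0, 3))]
    return acceptor[:pos] + base + acceptor[pos + 1:]


@dataclass
class _PlannedGene:
    gene_id: str
    sl_class: str
    origin: str
    offset: int
    cds: str


@dataclass
class _Unit:
    kind: str                      # single | operon | paralog_pair
    genes: list[_PlannedGene]
    icrs: list[int] = field(default_factory=list)
    major_offset: int = 0
    strand: str = "+"
    label: str = ""


def _allocate_counts(config: SimConfig) -> tuple[list[str], int, int]:
    """Split single genes over genic origins; derive novel/unmappable counts.

    Genic origins (annotated/minor/major) are allocated over the single
    genes by largest remainder; novel-site and unmappable fractions are
    realised as standalone tags scaled so the overall tag mix matches the
    configured proportions.
    """
    f_ann, f_min, f_maj, f_nov, f_unm = config.fractions
    genic = f_ann + f_min + f_maj
    if config.n_single_genes > 0 and genic <= 0:
        raise SimGenerationError(
            "single genes configured but all genic tag fractions are zero"
        )
    if genic <= 0:
        return [], round(f_nov * 10), round(f_unm * 10)
    total = config.n_single_genes / genic
    raw = [f * config.n_single_genes / genic for f in (f_ann, f_min, f_maj)]
    floors = [int(x) for x in raw]
    short = config.n_single_genes - sum(floors)
    order = sorted(range(3), key=lambda i: (raw[i] - floors[i], -i), reverse=True)
    for i in order[:short]:
        floors[i] += 1
    origins = (
        ["annotated_start"] * floors[0]
        + ["minor_offset"] * floors[1]
        + ["major_offset"] * floors[2]
    )
    return origins, int(round(f_nov * total)), int(round(f_unm * total))


# ---------------------------------------------------------------------------
# genome assembly


def _assemble_locus(
    rng: np.random.Generator, unit: _Unit, config: SimConfig
) -> tuple[str, list[tuple[_PlannedGene, int]]]:
    """Build one unit's transcript-oriented locus string.

    Returns ``(locus, [(gene, cds_offset_in_locus)])``. The locus starts
    with the (cassette) acceptor of its first planted element, so every
    acceptor lies inside the locus footprint.
    """
    parts: list[str] = []
    spans: list[tuple[_PlannedGene, int]] = []
    acceptor_offsets: list[int] = []
    pos = 0
    if unit.kind == "single" and unit.major_offset:
        d = unit.major_offset
        body = unit.genes[0].upstream_body  # type: ignore[attr-defined]
        parts.append(ACCEPTOR)
        acceptor_offsets.append(pos)
        pos += 7
        parts.append(body)                 # length d - 7
        pos += len(body)
    parts.append(ACCEPTOR)                 # first gene's acceptor
    acceptor_offsets.append(pos)
    pos += 7
    for gi, gene in enumerate(unit.genes):
        spans.append((gene, pos))
        parts.append(gene.cds)
        pos += len(gene.cds)
        if gi < len(unit.genes) - 1:
            icr = unit.icrs[gi]
            parts.append(_filler(rng, icr))
            pos += icr
    chars = list("".join(parts))
    # stamp acceptors of non-first genes; ICR < 7 overwrites the CDS tail
    for gene, off in spans[1:]:
        chars[off - 7 : off] = list(ACCEPTOR)
        acceptor_offsets.append(off - 7)
    for gene, off in spans:
        if gene.origin == "minor_offset":
            acceptor_offsets.append(off + gene.offset - 7)
    if config.acceptor_mode == "degraded":
        for aoff in acceptor_offsets:
            chars[aoff : aoff + 7] = list(_degrade(rng, ACCEPTOR))
    return "".join(chars), spans


def generate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Emit a synthetic genome, its gene catalog, and the ground truth.

    Raises :class:`SimSizingError` when the configured layout does not fit
    the chromosome length, naming the offending chromosome and unit.
    """
    rng = np.random.default_rng(config.seed)
    L = config.cds_length
    tag_len = config.tag_length
    used_tags: set[str] = set()

    single_origins, n_novel, n_unmap = _allocate_counts(config)

    units: list[_Unit] = []
    gene_counter = 0

    def next_gid() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:04d}"

    # standalone genes are SL1 spliced (SL2 marks operon-internal genes);
    # SL2 / SL1-SL2 diversity comes from the configured operons
    for idx, origin in enumerate(single_origins):
        sl = "SL1"
        d = 0
        cds = _make_cds(rng, L, tag_len, used_tags)
        unit = _Unit("single", [], label=f"single[{idx}]")
        if origin == "minor_offset":
            d = int(rng.integers(config.minor_offset_range[0],
                                 config.minor_offset_range[1] + 1))
            cds = _embed_minor(rng, cds, d, tag_len, used_tags)
        elif origin == "major_offset":
            d = int(rng.integers(config.major_offset_range[0],
                                 config.major_offset_range[1] + 1))
            unit.major_offset = d
        gene = _PlannedGene(next_gid(), sl, origin, d, cds)
        if origin == "major_offset":
            gene.upstream_body = _make_body(rng, d - 7, tag_len, used_tags)  # type: ignore[attr-defined]
        unit.genes.append(gene)
        units.append(unit)
    for oi, (patterns, icrs) in enumerate(config.operon_specs):
        genes = [
            _PlannedGene(next_gid(), sl, "annotated_start", 0,
                         _make_cds(rng, L, tag_len, used_tags))
            for sl in patterns
        ]
        units.append(_Unit("operon", genes, icrs=list(icrs), label=f"operon[{oi}]"))
    for pi in range(config.n_paralog_pairs):
        cds1 = _make_cds(rng, L, tag_len, used_tags)
        cds2 = _make_cds(rng, L, tag_len, used_tags)
        used_tags.discard(cds2[:tag_len])
        cds2 = cds1[:tag_len] + cds2[tag_len:]
        genes = [
            _PlannedGene(next_gid(), "SL1", "paralog_seed", 0, cds1),
            _PlannedGene(next_gid(), "SL1", "paralog_seed", 0, cds2),
        ]
        units.append(_Unit("paralog_pair", genes, icrs=[config.paralog_gap],
                           label=f"paralog[{pi}]"))

    for u in units:
        u.strand = "+" if rng.integers(0, 2) == 0 else "-"

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom: dict[str, list[_Unit]] = {c: [] for c in chroms}
    for i, u in enumerate(units):
        per_chrom[chroms[i % len(chroms)]].append(u)
    novel_per_chrom = {c: 0 for c in chroms}
    for i in range(n_novel):
        novel_per_chrom[chroms[i % len(chroms)]] += 1

    genome: dict[str, str] = {}
    truth_genes: list[TruthGene] = []
    truth_operons: list[dict] = []
    truth_paralogs: list[dict] = []
    truth_tags: list[TruthTag] = []
    gene_models: list[GeneModel] = []
    protected: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    planted: list[tuple[str, str, int, str]] = []  # sequence, chrom, start0, strand
    operon_counter = 0

    for chrom in chroms:
        buf = list(_background(rng, config.chromosome_length, config.background_gc))
        cursor = config.margin
        for unit in per_chrom[chrom]:
            cursor += config.base_gap + int(rng.integers(0, 300))
            locus, spans = _assemble_locus(rng, unit, config)
            end = cursor + len(locus)
            if end > config.chromosome_length - config.margin:
                raise SimSizingError(
                    f"{chrom}: unit {unit.label} ends at {end} bp, beyond "
                    f"usable length of chromosome_length "
                    f"{config.chromosome_length}"
                )
            buf[cursor:end] = list(revcomp(locus) if unit.strand == "-" else locus)
            protected[chrom].append((cursor, end))
            op = _register_unit(
                unit, chrom, cursor, locus, spans, config,
                truth_genes, gene_models, truth_tags, planted,
            )
            if unit.kind == "operon":
                operon_counter += 1
                op["operon_id"] = f"TOP{operon_counter:03d}"
                truth_operons.append(op)
            elif unit.kind == "paralog_pair":
                truth_paralogs.append(
                    {
                        "gene_ids": [g.gene_id for g in unit.genes],
                        "sequence": unit.genes[0].cds[:tag_len],
                    }
                )
            cursor = end
        for _ in range(novel_per_chrom[chrom]):
            pos = cursor + 3001
            body = _make_body(rng, 78, tag_len, used_tags)
            cassette = ACCEPTOR + body
            if config.acceptor_mode == "degraded":
                cassette = _degrade(rng, ACCEPTOR) + body
            end = pos + len(cassette)
            if end > config.chromosome_length - config.margin:
                raise SimSizingError(
                    f"{chrom}: novel cassette ends at {end} bp, beyond usable "
                    f"length of chromosome_length {config.chromosome_length}"
                )
            buf[pos:end] = list(cassette)
            protected[chrom].append((pos, end))
            tag_seq = body[:tag_len]
            truth_tags.append(
                TruthTag(tag_seq, "SL1", "novel_site", 0, None, chrom, pos + 8, "+")
            )
            planted.append((tag_seq, chrom, pos + 7, "+"))
            cursor = end
        genome[chrom] = "".join(buf)

    _enforce_tag_uniqueness(genome, protected, planted)

    for _ in range(n_unmap):
        for _attempt in range(1000):
            seq = "".join(rng.choice(_BASES, size=tag_len))
            rc = revcomp(seq)
            if not any(seq in ctg or rc in ctg for ctg in genome.values()):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SimGenerationError("could not sample an unmappable tag")
        truth_tags.append(TruthTag(seq, "SL1", "unmappable", 0, None, None, None, None))

    truth = GroundTruth(
        genes=truth_genes,
        operons=truth_operons,
        paralog_sets=truth_paralogs,
        tags=truth_tags,
        config=asdict(config),
    )
    return genome, gene_models, truth


def _register_unit(
    unit: _Unit,
    chrom: str,
    cursor: int,
    locus: str,
    spans: list[tuple[_PlannedGene, int]],
    config: SimConfig,
    truth_genes: list[TruthGene],
    gene_models: list[GeneModel],
    truth_tags: list[TruthTag],
    planted: list[tuple[str, str, int, str]],
) -> dict:
    """Record coordinates, truth entries and planned tags for one unit."""
    tag_len = config.tag_length
    strand = unit.strand
    locus_len = len(locus)
    ids: list[str] = []
    for gene, off in spans:
        a0, b0 = off, off + len(gene.cds)   # locus-internal, 0-based half-open
        if strand == "+":
            cds_start, cds_end = cursor + a0 + 1, cursor + b0
            exon_start = cds_start
        else:
            cds_start = cursor + (locus_len - b0) + 1
            cds_end = cursor + (locus_len - a0)
            exon_start = cds_end
        gene_models.append(
            GeneModel(gene.gene_id, chrom, strand, cds_start, cds_end, (exon_start,))
        )
        truth_genes.append(
            TruthGene(gene.gene_id, chrom, strand, cds_start, cds_end,
                      [exon_start], None, gene.sl_class, gene.origin)
        )
        ids.append(gene.gene_id)

        if gene.sl_class == "unknown":
            continue
        if gene.origin == "minor_offset":
            tag_off, offset = off + gene.offset, gene.offset
        elif gene.origin == "major_offset":
            tag_off, offset = 7, gene.offset   # cassette body starts at 7
        else:
            tag_off, offset = off, 0
        tag_seq = locus[tag_off : tag_off + tag_len]
        if strand == "+":
            start0 = cursor + tag_off
            five_prime = start0 + 1
        else:
            start0 = cursor + (locus_len - tag_off - tag_len)
            five_prime = cursor + (locus_len - tag_off)
        labels = ["SL1", "SL2"] if gene.sl_class == "SL1/SL2" else [gene.sl_class]
        for lab in labels:
            truth_tags.append(
                TruthTag(tag_seq, lab, gene.origin, offset, gene.gene_id,
                         chrom, five_prime, strand)
            )
        planted.append((tag_seq, chrom, start0, strand))
    return {
        "operon_id": "",
        "gene_ids": ids,
        "icrs": list(unit.icrs),
        "sl_pattern": [g.sl_class for g, _ in spans],
    }


def _enforce_tag_uniqueness(
    genome: dict[str, str],
    protected: dict[str, list[tuple[int, int]]],
    planted: list[tuple[str, str, int, str]],
) -> None:
    """Break accidental background copies of planted tag sequences.

    Each planted sequence must occur exactly at its planted loci (paralog
    seeds at two). An extra occurrence outside all planted intervals gets
    one deterministic base edit; a clash inside a planted locus is a
    generation error.
    """
    expected: dict[str, set[tuple[str, int]]] = {}
    for seq, chrom, start0, _strand in planted:
        expected.setdefault(seq, set()).add((chrom, start0))
    mutable = {c: list(s) for c, s in genome.items()}
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for _round in range(20):
        dirty = False
        for seq, sites in expected.items():
            rc = revcomp(seq)
            for chrom, contig_list in mutable.items():
                contig = "".join(contig_list)
                for query in (seq, rc) if rc != seq else (seq,):
                    pos = contig.find(query)
                    while pos != -1:
                        if (chrom, pos) not in sites:
                            free = [
                                i for i in range(pos, pos + len(seq))
                                if not any(a <= i < b for a, b in protected[chrom])
                            ]
                            if not free:
                                raise SimGenerationError(
                                    f"planted tag {seq} collides with another "
                                    f"planted locus at {chrom}:{pos + 1}"
                                )
                            contig_list[free[0]] = flip[contig_list[free[0]]]
                            dirty = True
                        pos = contig.find(query, pos + 1)
        if not dirty:
            break
    else:  # pragma: no cover
        raise SimGenerationError("tag uniqueness repair did not converge")
    for c in genome:
        genome[c] = "".join(mutable[c])


def generate_tags(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> list[TagRecord]:
    """Emit the deduplicated tag table for a generated genome.

    Tags are re-extracted from the genome at their planted coordinates
    (guaranteeing exact coding-strand substrings), observation counts are
    drawn from a geometric distribution, and records are deduplicated per
    (sequence, SL class).
    """
    rng = np.random.default_rng([config.seed, 1])
    observations: list[tuple[str, str]] = []
    for t in truth.tags:
        if t.origin == "unmappable":
            seq = t.sequence
        else:
            contig = genome[t.chrom]
            if t.strand == "+":
                seq = contig[t.start - 1 : t.start - 1 + config.tag_length]
            else:
                seq = revcomp(contig[t.start - config.tag_length : t.start])
            if seq != t.sequence:
                raise SimGenerationError(
                    f"tag at {t.chrom}:{t.start}({t.strand}) does not match "
                    "its planned sequence"
                )
        count = int(rng.geometric(config.count_geometric_p))
        observations.extend([(seq, t.sl_class)] * count)
    return dedupe_tags(observations, min_length=min(10, config.tag_length))
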