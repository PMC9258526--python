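"""Comparative analyses: operon conservation, catalog overlap, paralog
discovery from multi-mapping tags, annotation-version transitions, and the
gene-set enrichment statistic.

Ortholog maps are query->reference and may be one-to-many (a single query
gene can be orthologous to two reference genes); conservation classes are
evaluated over all image combinations.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotate import ExonCall, GeneModel
from .operons import OperonModel
from .search import TagMatch

CONSERVATION_CLASSES = ("exact", "partial", "novel_mixed", "novel_divergent")
OVERLAP_CLASSES = ("identical", "same_start", "same_end", "overlap", "none")


@dataclass
class ParalogSet:
    """Genes at distinct loci sharing identical 5' tag sequence(s)."""

    member_gene_ids: frozenset[str]
    seed_tag_ids: frozenset[str]
    annotation_match: str | None = None   # exact | partial | none
    same_chromosome: bool | None = None
    min_member_igr: int | None = None


def classify_operon_conservation(
    operon: OperonModel,
    ortholog_map: Mapping[str, set[str]],
    reference_operons: Mapping[str, Sequence[str]],
) -> str:
    """Conservation class of one operon against a reference operon catalog.

    * ``exact`` -- every member has an ortholog and, for some reference
      operon, each member has an image inside it and the images jointly
      cover its entire membership;
    * ``partial`` -- at least one member's ortholog lies in a reference
      operon but the exact condition fails;
    * ``novel_mixed`` -- members have orthologs, but none inside any
      reference operon;
    * ``novel_divergent`` -- no member has an ortholog at all.
    """
    images = [set(ortholog_map.get(g, set())) for g in operon.gene_ids]
    all_images: set[str] = set().union(*images) if images else set()
    ref_membership = {oid: set(genes) for oid, genes in reference_operons.items()}
    hit_operons = {
        oid for oid, members in ref_membership.items() if members & all_images
    }
    if not any(images):
        return "novel_divergent"
    if not hit_operons:
        return "novel_mixed" if all_images else "novel_divergent"
    if all(img for img in images):
        for oid in hit_operons:
            ref = ref_membership[oid]
            if all(img & ref for img in images) and ref <= all_images:
                return "exact"
    return "partial"


def compare_operon_catalogs(
    ours: Mapping[str, Sequence[str]],
    theirs: Mapping[str, Sequence[str]],
) -> dict[str, str]:
    """Best overlap class of each of our operons against another catalog.

    Classes in precedence order: ``identical`` (same ordered gene list),
    ``same_start`` (first genes equal, sets differ), ``same_end`` (last
    genes equal, sets differ), ``overlap`` (any shared gene), ``none``.
    """
    rank = {c: i for i, c in enumerate(OVERLAP_CLASSES)}
    out: dict[str, str] = {}
    for oid, genes in ours.items():
        genes = list(genes)
        best = "none"
        for tgenes in theirs.values():
            tgenes = list(tgenes)
            if genes == tgenes:
                cls = "identical"
            elif genes[0] == tgenes[0]:
                cls = "same_start"
            elif genes[-1] == tgenes[-1]:
                cls = "same_end"
            elif set(genes) & set(tgenes):
                cls = "overlap"
            else:
                cls = "none"
            if rank[cls] < rank[best]:
                best = cls
        out[oid] = best
    return out


def _overlapping_genes(
    match: TagMatch, genes: Sequence[GeneModel]
) -> list[str]:
    """Same-strand genes whose span contains the tag placement."""
    return [
        g.gene_id
        for g in genes
        if g.chrom == match.chrom
        and g.strand == match.strand
        and match.start >= g.cds_start
        and match.end <= g.cds_end
    ]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_paralog_sets(
    multi_matches: Mapping[str, Sequence[TagMatch]],
    genes: Sequence[GeneModel],
) -> list[ParalogSet]:
    """Paralog sets seeded by tags with several retained placements.

    Each multi-hit tag's placements are mapped to overlapping same-strand
    genes (placements outside any gene are dropped); tags hitting >= 2
    distinct genes seed a set, and sets sharing a gene are merged.
    Sets are returned sorted by their smallest member gene ID.
    """
    uf = _UnionFind()
    tag_genes: dict[str, set[str]] = {}
    for tag_id, matches in multi_matches.items():
        hit = set()
        for m in matches:
            hit.update(_overlapping_genes(m, genes))
        if len(hit) >= 2:
            tag_genes[tag_id] = hit
            ordered = sorted(hit)
            for g in ordered[1:]:
                uf.union(ordered[0], g)
    components: dict[str, set[str]] = defaultdict(set)
    seeds: dict[str, set[str]] = defaultdict(set)
    for tag_id, hit in tag_genes.items():
        root = uf.find(next(iter(sorted(hit))))
        components[root].update(hit)
        seeds[root].add(tag_id)
    sets = [
        ParalogSet(frozenset(members), frozenset(seeds[root]))
        for root, members in components.items()
    ]
    sets.sort(key=lambda s: min(s.member_gene_ids))
    return sets


def classify_paralog_sets(
    sets: Sequence[ParalogSet],
    annotated_groups: Sequence[set[str]],
    genes: Sequence[GeneModel],
) -> list[ParalogSet]:
    """Annotate paralog sets against known paralog groups and locations.

    ``exact`` -- the set equals an annotated group; ``partial`` -- it
    intersects one; ``none`` otherwise. Same-chromosome sets additionally
    get the minimum pairwise intergenic gap between members.
    """
    by_id = {g.gene_id: g for g in genes}
    out: list[ParalogSet] = []
    for ps in sets:
        members = set(ps.member_gene_ids)
        if any(members == grp for grp in annotated_groups):
            match = "exact"
        elif any(members & grp for grp in annotated_groups):
            match = "partial"
        else:
            match = "none"
        chroms = {by_id[g].chrom for g in members if g in by_id}
        same_chrom = len(chroms) == 1 and len(members) >= 2
        min_igr: int | None = None
        if same_chrom:
            models = sorted(
                (by_id[g] for g in members if g in by_id),
                key=lambda g: g.cds_start,
            )
            gaps = [
                b.cds_start - a.cds_end - 1
                for a, b in zip(models, models[1:])
            ]
            if gaps:
                min_igr = min(gaps)
        out.append(
            ParalogSet(ps.member_gene_ids, ps.seed_tag_ids, match, same_chrom, min_igr)
        )
    return out


def compare_annotation_versions(
    calls_a: Sequence[ExonCall],
    calls_b: Sequence[ExonCall],
) -> tuple[dict[str, tuple[str, str]], Counter]:
    """Per-tag category transitions between two gene catalogs.

    The same tag set classified against an older (A) and newer (B)
    catalog yields one ``(category_A -> category_B)`` transition per tag.
    Tags with no call against A, or whose A-call found no gene within the
    novel-exon radius (the locus was unannotated in A), count as
    ``absent``. Returns the per-tag transitions and summary counts per
    transition.
    """
    cat_a = {c.tag_id: c.category for c in calls_a}
    transitions: dict[str, tuple[str, str]] = {}
    for call in sorted(calls_b, key=lambda c: c.tag_id):
        a = cat_a.get(call.tag_id, "absent")
        if a == "novel":
            a = "absent"
        transitions[call.tag_id] = (a, call.category)
    summary = Counter(transitions.values())
    return transitions, summary


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a set of size ``K`` and a draw of size
    ``n`` from a universe of ``N`` genes. Exact integer combinatorics;
    returns 1.0 when ``k == 0``.
    """
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    total = math.comb(N, n)
    upper = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return upper / total
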