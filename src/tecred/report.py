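"""Summary tables: counts and percentage shares per category/class.

The report mirrors the study-style tables: tag totals per SL class, tag
match categories, genes per SL class, single- vs multiple-transcript gene
breakdowns, operon sizes and support, and operon conservation classes.
Shares are rounded half-up at the table's printed precision.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

from .annotate import GeneCall
from .operons import OperonModel


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_shares(
    counts: Mapping[str, int], decimals: int = 1
) -> dict[str, float | None]:
    """Percentage share of each row in the column total.

    Rounding is half-up at ``decimals`` places; a zero total yields absent
    (None) shares rather than a division error.
    """
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        return {k: None for k in counts}
    return {
        k: round_half_up(100.0 * v / total, decimals) for k, v in counts.items()
    }


def tag_overview_table(
    n_tags_by_class: Mapping[str, int],
    n_matched_by_class: Mapping[str, int],
    n_unique_by_class: Mapping[str, int],
    n_multi_by_class: Mapping[str, int],
) -> pd.DataFrame:
    """Per-SL-class tag totals: unique tags, matched, unique hits, multi hits."""
    classes = ["All", "SL1", "SL2"]
    rows = []
    for cls in classes:
        if cls == "All":
            pick = lambda d: sum(d.values())  # noqa: E731
        else:
            pick = lambda d, c=cls: d.get(c, 0)  # noqa: E731
        rows.append(
            {
                "class": cls,
                "total_unique_tags": pick(n_tags_by_class),
                "matches_in_genome": pick(n_matched_by_class),
                "unique_hits": pick(n_unique_by_class),
                "multiple_hits": pick(n_multi_by_class),
            }
        )
    return pd.DataFrame(rows)


CATEGORY_LABELS = {
    "1a": "1a",
    "1b": "1b",
    "minor_mp": "Minor misprediction",
    "major_mp": "Major misprediction",
    "other": "Others",
    "novel": "Novel",
}


def category_table(
    counts_by_class: Mapping[str, Mapping[str, int]], decimals: int = 1
) -> pd.DataFrame:
    """Tag-match categories x SL class with total shares (one decimal)."""
    cats = ["1a", "1b", "minor_mp", "major_mp", "other", "novel"]
    classes = sorted(counts_by_class)
    totals = {
        cat: sum(counts_by_class[cls].get(cat, 0) for cls in classes)
        for cat in cats
    }
    shares = tabulate_shares(totals, decimals)
    rows = []
    for cat in cats:
        row = {"category": CATEGORY_LABELS[cat]}
        for cls in classes:
            row[cls] = counts_by_class[cls].get(cat, 0)
        row["total"] = totals[cat]
        row["share_pct"] = shares[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def gene_sl_table(gene_calls: Sequence[GeneCall], decimals: int = 0) -> pd.DataFrame:
    """Genes per spliced-leader class with whole-percent shares."""
    counts = {"SL1": 0, "SL2": 0, "SL1/SL2": 0}
    for gc in gene_calls:
        if gc.sl_class in counts and not gc.gene_id.startswith("novel:"):
            counts[gc.sl_class] += 1
    shares = tabulate_shares(counts, decimals)
    return pd.DataFrame(
        [
            {"sl_class": k, "n_genes": v, "share_pct": shares[k]}
            for k, v in counts.items()
        ]
    )


def transcript_multiplicity_tables(
    gene_calls: Sequence[GeneCall],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single- and multiple-transcript gene breakdowns by category x SL."""
    real = [g for g in gene_calls if not g.gene_id.startswith("novel:")]
    singles = [g for g in real if g.multiplicity == "single_transcript"]
    multis = [g for g in real if g.multiplicity == "multiple_transcripts"]

    def table(group: list[GeneCall]) -> pd.DataFrame:
        rows: dict[str, dict[str, int]] = {}
        for g in group:
            row = rows.setdefault(g.composite_category, {"SL1": 0, "SL2": 0,
                                                         "SL1/SL2": 0})
            if g.sl_class in row:
                row[g.sl_class] += 1
        recs = []
        for cat in sorted(rows):
            rec = {"category": cat, **rows[cat]}
            rec["total"] = sum(rows[cat].values())
            recs.append(rec)
        return pd.DataFrame(recs)

    return table(singles), table(multis)


def operon_size_table(operons: Sequence[OperonModel]) -> pd.DataFrame:
    """Operon counts by number of genes, split by support level."""
    rows = []
    for support in ("tag_supported", "predicted"):
        group = [o for o in operons if o.support == support and not o.sl1_type]
        sizes = {}
        for o in group:
            sizes[o.n_genes] = sizes.get(o.n_genes, 0) + 1
        row = {"support": support, "n_operons": len(group)}
        for size in range(2, max(sizes, default=2) + 1):
            row[f"{size}_genes"] = sizes.get(size, 0)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def conservation_table(
    classes: Mapping[str, str], decimals: int = 1
) -> pd.DataFrame:
    """Operon conservation classes with shares of the classified total."""
    counts = {
        "exact": 0,
        "partial": 0,
        "novel_mixed": 0,
        "novel_divergent": 0,
    }
    for cls in classes.values():
        counts[cls] += 1
    counts_out = dict(counts)
    counts_out["novel"] = counts["novel_mixed"] + counts["novel_divergent"]
    shares = tabulate_shares(counts, decimals)
    total = sum(counts.values())
    novel_share = (
        None if total == 0
        else round_half_up(100.0 * counts_out["novel"] / total, decimals)
    )
    rows = [
        {"class": "exact", "n": counts["exact"], "share_pct": shares["exact"]},
        {"class": "partial", "n": counts["partial"], "share_pct": shares["partial"]},
        {"class": "novel", "n": counts_out["novel"], "share_pct": novel_share},
        {"class": "novel_mixed", "n": counts["novel_mixed"],
         "share_pct": shares["novel_mixed"]},
        {"class": "novel_divergent", "n": counts["novel_divergent"],
         "share_pct": shares["novel_divergent"]},
    ]
    return pd.DataFrame(rows)


def catalog_overlap_table(overlap_classes: Mapping[str, str]) -> pd.DataFrame:
    """Counts per overlap class against an external operon catalog."""
    counts = {"identical": 0, "same_start": 0, "same_end": 0, "overlap": 0,
              "none": 0}
    for cls in overlap_classes.values():
        counts[cls] += 1
    return pd.DataFrame(
        [{"match_type": k, "n_operons": v} for k, v in counts.items()]
    )
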