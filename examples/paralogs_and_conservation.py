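"""Paralog discovery from multi-mapping tags and operon conservation.

A tag that maps perfectly to two gene loci marks a candidate gene
duplication; sets sharing genes are merged. Operons are classified
against a reference species' operon catalog through an ortholog map.
"""

from tecred import (
    GeneModel,
    TagMatch,
    build_paralog_sets,
    classify_operon_conservation,
    compare_operon_catalogs,
)
from tecred.operons import OperonModel

genes = [
    GeneModel("dupA1", "chrII", "+", 5_000, 5_900),
    GeneModel("dupA2", "chrII", "+", 40_000, 40_900),
    GeneModel("dupB", "chrII", "+", 60_000, 60_900),
]
multi = {
    "tag07": [TagMatch("tag07", "chrII", 5_000, 5_013, "+"),
              TagMatch("tag07", "chrII", 40_000, 40_013, "+")],
    "tag19": [TagMatch("tag19", "chrII", 40_050, 40_063, "+"),
              TagMatch("tag19", "chrII", 60_000, 60_013, "+")],
}
for ps in build_paralog_sets(multi, genes):
    print("paralog set:", sorted(ps.member_gene_ids),
          "seeded by", sorted(ps.seed_tag_ids))

# conservation: both members orthologous to the full reference operon
op = OperonModel("op1", ["dupA1", "dupB"], [100], "tag_supported")
orthologs = {"dupA1": {"ceg1"}, "dupB": {"ceg2"}}
reference = {"CEOP1": ["ceg1", "ceg2"], "CEOP2": ["ceg3", "ceg4", "ceg5"]}
print("conservation class:",
      classify_operon_conservation(op, orthologs, reference))

overlap = compare_operon_catalogs(
    {"op1": ["g1", "g2", "g3"]}, {"x1": ["g1", "g2"], "x2": ["g9"]}
)
print("catalog overlap:", overlap)

# The two seed tags share dupA2, so the sets merge into one three-gene
# family. The operon is an exact match (its ortholog image equals one
# reference operon), and op1 vs x1 share a first gene -> 'same_start'.
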