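"""Infer operons from spliced-leader classes and intercistronic distances.

Downstream genes of nematode operons are SL2 (or SL1+SL2) trans-spliced;
chaining consecutive same-strand SL2-class genes and attaching a known
SL1-spliced upstream gene reconstructs the operon. Adjacent SL1 genes with
no gap form the rarer SL1-type operons.
"""

from tecred import GeneModel, build_operons, compute_igr, detect_sl1_type

# five genes on one strand: an SL1 gene heading two SL2-class genes,
# then two SL1 genes sitting back-to-back (an SL1-type candidate)
genes = [
    GeneModel("gene1", "chrI", "+", 1_000, 1_900),
    GeneModel("gene2", "chrI", "+", 2_051, 2_950),   # ICR 150 to gene1
    GeneModel("gene3", "chrI", "+", 3_031, 3_930),   # ICR 80 to gene2
    GeneModel("gene4", "chrI", "+", 10_000, 10_900),
    GeneModel("gene5", "chrI", "+", 10_901, 11_800),  # ICR 0 to gene4
]
sl = {"gene1": "SL1", "gene2": "SL2", "gene3": "SL1/SL2",
      "gene4": "SL1", "gene5": "SL1"}

for op in build_operons(genes, sl):
    print(f"{op.operon_id}: {'-'.join(op.gene_ids)} "
          f"ICRs={op.icr_bp} support={op.support} hybrid={op.hybrid}")
for op in detect_sl1_type(genes, sl):
    print(f"SL1-type: {'-'.join(op.gene_ids)} ICRs={op.icr_bp} "
          f"warnings={op.warnings}")
print("gene4->gene5 intergenic distance:",
      compute_igr(genes[3], genes[4]), "bp")

# The first three genes form one tag-supported hybrid operon (gene3 is
# spliced by both leaders); gene4/gene5 are directly adjacent SL1 genes,
# reported as an SL1-type operon with zero intercistronic space.
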