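"""Generate a synthetic trans-splicing study and classify every tag.

A three-chromosome genome carries 60 genes (27 standalone, 10 operons,
3 duplicated pairs); each expressed gene emits a 14 nt 5' tag at its
annotated start. The pipeline maps the tags, checks splice acceptors,
and classifies each tag-implied start site against the gene catalog.
"""

from collections import Counter

from tecred import RunConfig, SimConfig, generate_genome, generate_tags, run_pipeline

config = SimConfig(seed=1)
genome, genes, truth = generate_genome(config)
tags = generate_tags(genome, truth, config)
result = run_pipeline(RunConfig(), tags=tags, genome=genome, genes=genes,
                      write=False)

print(f"simulated genes: {len(genes)}, emitted tag records: {len(tags)}")
print("tag mapping status:", dict(Counter(result.status_by_tag.values())))
print("start-site categories:", dict(Counter(c.category for c in result.calls)))
print(result.tables["genes_by_sl"].to_string(index=False))

# Every tag was planted at an annotated start, so every call is category 1a
# (start coincides with an annotated first exon) and the SL1/SL2/hybrid
# gene counts match the simulated splicing classes exactly. The three
# 'multi' tags are the paralog seeds, which map twice by construction.
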