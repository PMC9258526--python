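"""Gene-set enrichment and report-table percentage shares.

The overlap between operon genes and a functional gene set (e.g. germline
genes) is tested with the exact upper-tail hypergeometric probability;
summary tables report category counts with half-up rounded shares.
"""

from tecred import hypergeometric_enrichment, tabulate_shares

# 40 of 60 operon genes appear in a 300-gene germline set drawn from a
# 2,000-gene universe: how surprising is that overlap?
p = hypergeometric_enrichment(k=40, K=300, n=60, N=2_000)
print(f"P(X >= 40) = {p:.3e}")

# shares of start-site categories, printed at one decimal
counts = {"1a": 5_079, "1b": 23, "minor_mp": 336, "major_mp": 930, "other": 27}
print("category shares (%):", tabulate_shares(counts, decimals=1))

# A p-value this small says the operon gene set is heavily enriched for
# the functional class; the share table shows ~79% of tag matches confirm
# annotated first-exon starts.
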