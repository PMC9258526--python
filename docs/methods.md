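# Methods

## Model and assumptions

The analysis treats a 5′ tag as an exact, error-free excerpt of a mature
mRNA's 5′ end, taken immediately downstream of the spliced-leader (SL)
trans-splice junction. Three assumptions follow:

1. **Exact mapping.** Tags are short (~14 nt), so mapping allows no
   mismatches: one mismatch would trade a small gain in sensitivity for a
   large loss in specificity at this length. Both strands are searched;
   minus-strand placements are reported in forward-reference coordinates
   with strand `-`. All external coordinates are 1-based inclusive (GFF3
   convention); the BED6 exporter converts to 0-based half-open.
2. **Acceptor support.** A genuine trans-splice site carries the acceptor
   consensus `TTTTCAG` directly upstream of the tag. The scorer awards
   per-position weights `(1,1,1,1,2,3,3)` for matches: the terminal AG
   dinucleotide is invariant in splice acceptors and gets the top weight,
   the preceding C the next, and the weakly conserved T tract one each.
   The weight numbers themselves are a package choice (only the ranking —
   conserved bases dominate — is biologically fixed) and the table is
   configurable. Placements scoring below 6 (half the maximum 12; enough
   to demand the AG plus about half the remaining consensus) are rejected
   as weak acceptors before any classification. Among a tag's surviving
   placements only those attaining the tag's maximum score are kept:
   a single survivor is a unique hit; ties are candidate paralogs.
3. **ORF plausibility.** The tag-implied CDS start is the first ATG at or
   downstream of the tag's 5′ end within `max_scan` = 3,000 bp, accepted
   only if no in-frame stop occurs within `min_orf_codons` = 25 codons.
   Both numbers are free parameters (defaults are echoed into every run
   header): 3 kb aligns the ATG scan window with the novel-exon radius so
   one coherent downstream window governs both decisions, and 25 codons
   excludes spurious micro-ORFs while retaining short genes.

## Start-site categories

Offsets are measured from the tag-implied ATG to the nearest same-strand
annotated exon start, signed, in transcript orientation:

| category | rule |
|---|---|
| 1a | offset 0 at a first-exon (CDS) start |
| 1b | offset 0 at an internal exon start |
| minor misprediction | 1 ≤ \|offset\| ≤ 20 (inclusive at 20) |
| major misprediction | \|offset\| > 20 and an exon lies ≤ 3,000 bp downstream |
| novel | no exon within 3,000 bp downstream |
| other | ambiguous: ATG exactly equidistant from two genes' exons |

For major mispredictions the reported gene and offset refer to the nearest
*downstream* exon (the gene whose model the tag would extend); for
1a/1b/minor they refer to the nearest exon overall. Distinct 5′ ends of a
gene are exact-position distinct (no fuzz window — tags are exact), and a
gene with ≥ 2 ends is a multiple-transcript gene. Composite labels for
multi-end genes: `{1a,1b}`, `{1a,minor}`, `{1a,major}` and pure-
misprediction sets get their named buckets; every other combination falls
into `others`, whose precise membership is a package convention.

## Intergenic distances and operons

IGR = (downstream CDS 5′ start) − (upstream 3′ boundary) − 1 in
transcription order; the 3′ boundary is the annotated 3′ UTR end when
present, else the CDS end (the fallback is recorded per pair). Adjacent
genes give 0; a nested or overlapping downstream gene gives a negative
value. Intercistronic regions (ICRs) are the same quantity between
consecutive operon members.

Operon chaining is purely SL-pattern driven: maximal runs of consecutive
same-strand SL2 or SL1/SL2 genes form the body; the model is
*tag-supported* when its first gene's SL class is known and SL1-capable
(SL1, or SL1/SL2 — hybrid operons imply SL1-capable first genes; a strict
mode demands pure SL1), otherwise *predicted*. A gene of unknown class
immediately upstream is excluded by default (an `include_unknown_head`
flag pulls it in). There is deliberately no hard distance cutoff — real
operons with > 2 kb ICRs exist — but links above 2 kb carry an
`icr_gt_2kb` warning and an optional `max_icr` splitter (off by default)
can cut long links. High-confidence operons are the tag-supported models
plus predicted models of ≥ 3 genes. Consecutive SL1 genes at ≤ 1 bp gap
are emitted separately as SL1-type operons; exactly 1 bp is flagged
`potential`. IGR distribution summaries exclude distances > 5,000 bp
(the exclusion count is reported) and histogram the rest in 500 bp bins
(100 bp for ICRs) plus one negative bin.

## Comparative analyses

Ortholog maps are query→reference and may be one-to-many. An operon is an
**exact** conservation match when every member has an ortholog and, for
some reference operon, each member has an image inside it and the images
jointly cover its membership — a reference operon with extra genes demotes
the match to **partial**, as does any unmapped member whose partners hit a
reference operon. **Novel** operons split into *mixed* (orthologs exist
but none sits in any reference operon) and *divergent* (no orthologs at
all). Catalog-overlap classes use the precedence identical > same start >
same end > overlap when an operon matches several counterparts.

Paralog sets are seeded by tags retaining several top-scoring placements:
placements are assigned to same-strand genes containing them, loci outside
any gene are dropped, sets need ≥ 2 distinct genes, and sets sharing a
gene are merged (union-find). Nested redundant tags are collapsed first —
by default only among multi-hit tags (a `collapse_globally` flag extends
it), keeping the longest sequence whose placements contain the shorter's.

The enrichment statistic is the exact upper-tail hypergeometric
probability computed with integer combinatorics (`math.comb`), so
extremely small probabilities are exact rather than underflowing; no
multiple-testing correction is applied since a single test is reported.
Annotation-version comparison classifies the same tag set against two
catalogs and tabulates per-tag category transitions; a tag whose old-
catalog call found no gene within the novel radius counts as *absent*
there (the locus was unannotated).

## Synthetic data: what it emulates, and what it does not

The generator lays out single genes, operons with configured SL patterns
and ICRs, and duplicated (paralog) loci across multiple chromosomes, on
both strands (50/50), each CDS preceded by a perfect `TTTTCAG` acceptor
(`degraded` mode mutates one non-AG consensus position per acceptor,
exercising the weighted scorer without destroying the mandatory AG). Tags
are planted at annotated starts, at minor offsets (10–20 bp inside the
CDS; offsets below 10 bp would collide with the planted acceptor, and the
1–20 bp boundary behaviour is instead exercised directly on constructed
catalogs), at major offsets (25–1,200 bp upstream cassettes), at novel
intergenic sites > 3 kb from every exon, and as rejection-sampled
unmappable sequences. Defaults are the reference desk-scale study: three
50 kb chromosomes, 60 genes total (27 single, 10 operons of 2–4 genes at
50–500 bp ICRs, 3 paralog pairs), noiseless tags at annotated starts.

Two construction guarantees make ground truth exact: coding filler is
drawn from {A,C,G} only, so no stop codon can arise in any reading frame
and every planted ATG passes the ORF check; and planted tag sequences are
kept globally unique (re-drawn on collision at planning time; accidental
background copies are broken by a single deterministic base edit outside
all planted loci). Acceptors are stamped after layout, so an ICR < 7 bp
(SL1-type operons) overwrites the upstream CDS tail — mirroring an
acceptor at the gene junction and invisible to every analysis stage.
Standalone genes are always SL1-spliced, as in real nematode genomes,
which also keeps the truth operon catalog identical to what the SL rule
can recover. Observation counts are drawn from a geometric distribution
(p = 0.5) purely as plumbing — the real count distribution is unknown and
no fidelity is claimed.

The simulator does **not** model sequencing errors, quality scores,
concatemer/ditag artifacts, alternative splicing within a gene, introns
(gene models are single-exon), overlapping or nested real genes, or
genome-assembly gaps. Passing tests therefore demonstrate the correctness
of the analysis logic under clean data — category boundaries, strand
handling, distance conventions, set algebra — not robustness to the noise
sources of a real tag library, where the acceptor gate and ORF checks do
the filtering work.

## Numerical conventions

Percentage shares are rounded half-up (`decimal.ROUND_HALF_UP`) at each
table's printed precision; zero totals yield absent shares, not division
errors. Tag IDs are zero-padded ordinals assigned after sorting by
(sequence, SL class), so outputs never depend on input order. All
randomness lives in the generator behind a single integer seed (analysis
stages are deterministic), and a fixed seed reproduces byte-identical
FASTA/GFF3/TSV/JSON outputs. Matches whose 7-mer acceptor context would
run off a contig edge are rejected (`contig_edge`) rather than padded.
The acceptance script scales the end-to-end study to the desk-scale
defaults above and its mapping cross-check to 200 random genomes of up to
50 kb; both sizes are package choices that keep the whole script in the
seconds range while exercising every code path.

## Known limitations

* Exon starts come from CDS coordinates; 5′ UTRs are not modelled, so a
  tag landing in a real 5′ UTR scores as a (minor/major) misprediction of
  the CDS start rather than a UTR-aware match.
* The `other` category implements one specific ambiguity rule (exact
  equidistance between two genes); real curation uses richer evidence.
* Paralog placement requires containment within an annotated CDS; a tag
  pair hitting one gene and one unannotated duplicate is not reported as
  a paralog set (the unannotated copy surfaces as a novel site instead).
* `compare_annotation_versions` keys transitions by tag, not by gene, so
  gene identity changes between catalog versions are handled implicitly
  through tag placement rather than through an ID-mapping table.
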