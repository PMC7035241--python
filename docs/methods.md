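# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that matter when reading the
code or its output.

## Coordinate and sequence conventions

Internally every interval is 0-based half-open; GTF (1-based closed) and VCF
(1-based) convert at the I/O boundary only. HGVS `c.` positions are 1-based
with c.1 at the A of the start ATG; UTR (negative) numbering is not
supported — only coding effects are in scope, and positions outside the CDS
raise an error carrying the nearest CDS boundary. Translation uses the
standard nuclear code and requires an in-frame stop inside the annotated
CDS; transcripts failing validation (internal stop, missing stop, ambiguity
base N inside the CDS, CDS outside exons, length not divisible by 3) are
skipped with a warning during genome-wide scans rather than aborting,
mirroring how tolerant annotation-scale scans must behave, but raise when
addressed directly.

## Isoform containment

For each gene with at least two coding transcripts, the longest- and
shortest-CDS transcripts are compared (spliced CDS length; ties broken by
lexicographically smallest transcript id, so results are deterministic;
intermediate isoforms are ignored and logged). The short isoform is called
an N-terminal truncation of the long one when

1. the genomic position of the short transcript's start ATG maps into the
   long transcript's CDS at frame offset 0 (an in-frame internal ATG at
   codon k+1), and
2. the short protein equals the long protein's suffix starting at residue
   k+1 — exact string equality, no gaps or mismatches.

Exact anchored containment is mathematically equivalent to demanding a
100%-identity, ungapped, full-length pairwise alignment, so no external
aligner is involved; a diagnostic `all_offsets` mode additionally reports
every ungapped offset at which the short protein occurs in the long one.
Identical CDS in both transcripts count as containment with truncation 0.
Transcripts of one gene on different contigs or strands produce a
structural-mismatch result (not contained), never an exception.

The filter cascade applies, in order: containment hit → membership in a
user-supplied essential-gene list → absence from a user-supplied
disease-annotation list → truncation strictly less than 50 residues. The
lists are plain one-column TSVs and are always inputs, never fetched; the
50-aa cutoff excludes isoform pairs so different in size that they likely
diverge functionally, and the comparison is strict (`< 50`, a gene at
exactly 50 is excluded). Survivor sets are nested by construction and the
cascade object enforces that invariant.

## Tissue isoform usage

The unique territory of each isoform is the set difference of exon unions
(half-open interval algebra). Reads are counted per unique-region set with
an overlap-of-one-base rule; a read spanning unique regions of both
isoforms increments both counts, matching per-region multi-coverage
counting (an assign-to-larger-overlap alternative exists but is off by
default). Counts are averaged across samples within a tissue *before* the
ratio s/(s+l) is formed — the tissue ratio is the usage of the pooled
average sample, not a mean of per-sample ratios. Tissues whose mean total
evidence falls below `min_count = 10` are left undefined; the threshold
prevents 0-or-1 ratios driven by single reads and is exposed in
configuration since nothing in the procedure dictates a particular value.
Variability is max − min over defined tissue ratios, needs at least two
defined tissues, and a gene is flagged when variability strictly exceeds
0.5. The canonical input is a counts TSV (sample, gene, short_count,
long_count) plus a sample→tissue map, so no alignment step is needed; a
BED-like read-interval path is provided for raw interval input.

## Variant consequences

SNVs are substituted in coding orientation (alleles reverse-complemented
for minus-strand transcripts), the affected codon retranslated, and the
change classified as missense, synonymous, stop-gained, stop-lost, or —
when codon 1's ATG is disrupted — start-loss, which is reported as `p.?`:
the downstream protein effect of losing a start codon is unknowable without
assuming a rescue ATG. A diagnostic lists in-frame downstream ATGs, which
is exactly the feature that makes an internal-ATG isoform vulnerable.

Insertions arrive VCF-style (left-anchored, one reference base) and are
internally re-expressed as "between c.i and c.i+1". Length-3n insertions
are in-frame (no frameshift); others shift the frame starting at the codon
containing c.(i+1). The mutant coding sequence is rebuilt and — because a
shifted frame ignores the old stop — continued through the 3'UTR, then
translated from the first affected codon to the first stop. The notation
`p.X{f}Y fs*{m}` records the reference residue at the first affected codon
f, the new residue there, and the stop's offset m counted with the first
affected codon as 1, so the new stop sits at protein position f + m − 1.
If no stop exists before the transcript end the dialect `fs*?` is emitted
and the offset left undefined. A 50-nt-rule flag (premature stop more than
50 nt upstream of the final exon junction) is attached as annotation only;
no decay prediction is claimed. Deletions, MNVs and splice-site effects are
out of scope.

## Runs of homozygosity and founder dating

Genotypes are read from a multi-sample VCF (GT:DP:GQ; multiallelic sites
dropped with a tally) and filtered at depth ≥ 10 and genotype quality ≥ 50,
both inclusive. ROH calling honors the four classic PLINK parameters —
min 5 SNPs, min 100 kb span, max 10 Mb inter-SNP gap, zero tolerated
heterozygotes — as a direct maximal-run caller: any heterozygote ends a
run, as does a gap violation. PLINK's sliding-window machinery (window
size, window-proportion thresholds) is deliberately not reproduced: with
zero tolerated window heterozygotes the window apparatus reduces to
het-free maximal runs, which the direct caller computes exactly and
testably (the suite checks equivalence against a brute-force enumeration).
Span is measured first-to-last SNP; input must arrive position-sorted (no
silent sort). A region flag restricts the scan around the focal locus.

The minimal shared segment across carriers is the intersection of each
sample's focal-variant-containing run (max of starts to min of ends); any
carrier lacking a focal ROH is a hard error naming the samples. Genetic
length comes from piecewise-linear interpolation of a (contig, bp, cM)
genetic-map table, with flat extrapolation outside the anchors (flagged).

Ages are estimated under a haplotype-erosion model: crossovers arrive at
1 per 100 cM per meiosis, so after g generations each of n independent
meiotic transmission paths retains an Exp(100/g)-cM segment on each side of
the focal variant; the shared segment takes the per-side minimum over
paths, making each side Exp(100/(n·g)) and E[L] = 200/(n·g) cM. The
method-of-moments estimate is ĝ = 200/(n·L); the 95% CI is a central
parametric bootstrap (lengths redrawn under ĝ, re-estimated, quantiles
taken; seeded, 2000 replicates by default). Two properties of this
estimator deserve emphasis. First, L is Gamma(2, 100/(n·g)) distributed,
so the estimator is heavy-tailed: a single realized segment dates a
mutation only to within a factor of a few, which the wide bootstrap CI
makes visible. Second, its sampling median is 2/1.6783 ≈ 1.19 times the
true g (the Gamma(2) median factor), a known, derivable bias of the
moment estimator that the test suite asserts in closed form rather than
hiding. The number of paths n depends on pedigree structure and is a
required user input — it is never guessed from the number of probands.
Calendar conversion multiplies by a configurable years-per-generation
(default 25; 23 reproduces the printed generations↔years pairing of the
motivating case). The genome-wide inbreeding coefficient F_ROH uses a
3.2 Gb genome-length denominator, the conventional round figure consistent
with the motivating case's printed 50 Mb ↔ 1/64 pairing.

## Synthetic data

The generators exist so that every stage is testable with no downloads;
all are byte-reproducible from (seed, config).

**Annotation.** Planted candidate genes have the two-promoter topology of
the motivating locus: a long transcript whose first exon carries the first
80 codons, a short transcript with its own noncoding first exon and a CDS
starting at an engineered in-frame internal ATG k codons in (k drawn from
5–40 by default, below the 80-codon first-exon span), both sharing all
downstream coding sequence. Negatives include genes whose short isoform
carries one amino-acid mismatch in a privately duplicated downstream exon
(in-frame ATG but containment fails), genes whose internal ATG sits at
frame offset 1 (containment anchored off-frame; rejection sampling keeps
the shifted frame stop-free where needed), genes with two unrelated coding
isoforms, and single-transcript genes. Roughly 40% of genes land on the
minus strand by reverse-complementing the whole local build. Essential and
disease labels are drawn independently (defaults 0.6 and 0.3) and written
as list TSVs consistent with the recorded truth.

**Expression.** Per gene × tissue, short counts are Binomial(depth, usage)
with long = depth − short, per sample (default depth 2000, 3 samples per
tissue, 4 tissues). Planted usage is either a one-tissue switch
(0.95 vs 0.2, giving variability 0.75, comfortably above the 0.5 flag
threshold) or flat 0.5. Counts are binomial, not negative-binomial: the
quantity under test is the ratio statistic, not dispersion-sensitive
differential expression; an overdispersion knob would add realism the
acceptance surface never probes.

**Probands.** An ancestral haplotype carrying the focal allele is eroded
per proband through 2 meiotic paths (consanguineous closure) exactly as in
the estimator's model; the retained interval is mapped from cM to bp by
inverse interpolation of the genetic map (uniform 1 cM/Mb over a 30 Mb
contig by default, markers every 50 kb). Probands are homozygous for the
ancestral alleles inside their retained interval; outside it they are
heterozygous with probability 0.5 per marker — the marker panel stands for
ascertained polymorphic sites, where heterozygosity outside an autozygous
segment is common. A configurable fraction of calls is emitted with
QC-failing DP or GQ. Because hom runs can extend a called ROH a few
markers past the true boundary (geometrically distributed overshoot), the
generator's truth interval and the called shared segment agree only up to
a few marker spacings, and the tests assert exactly that.

What the generators do **not** emulate: real exon/intron size
distributions, capture-density artifacts of exome sequencing (which make
real shared-ROH boundaries uncertain), linkage disequilibrium, allele
frequencies, sequencing error, or read-level data. Passing tests therefore
demonstrate correctness of the algorithms under their stated models, not
robustness to real-data messiness.

## Pipeline and reproducibility

A single YAML config drives scan → ratio → consequence (optional) →
roh → age; all thresholds default to the screen's canonical values
(truncation 50 aa, variability 0.5, ROH 5/100/10,000/0, DP 10, GQ 50) and
are recorded, along with input checksums and every seed, in a run manifest
whose hash is reproducible across reruns. Stage failures abort with a
stage-labeled error; machine output goes to files, logs to stderr. The
test-suite problem sizes (a ~20-gene genome, ~600-marker probands,
500–2000 simulation replicates) were chosen so the full suite exercises
every code path in seconds while keeping binomial/Monte-Carlo noise well
inside the asserted tolerances.
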