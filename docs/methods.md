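# Methods

## Scope and design

`polyterm` pairs an analysis pipeline for polyadenylation read-through,
distal poly(A)-site usage and repeat-element expression with a synthetic
data generator that produces the inputs with known ground truth. The
motivating biology is a germ-cell polyadenylation-factor knockout: the two
simulated conditions (labelled WT and KO by default) differ in exactly
three dials — the probability ρ that transcription reads through the
chosen poly(A) site, the fraction f of transcripts cleaved at the distal
site, and the LINE-1 transcription rate λ — while everything else
(genome, annotation, background rates) is shared. Every downstream
statistic can therefore be checked for parameter recovery rather than
against irreproducible external data.

Coordinates are 0-based half-open throughout; BED and PSL writers follow
those formats' native conventions. The library is unstranded (fragments of
double-stranded cDNA), so read strand is randomized at emission and all
overlap logic is strand-agnostic.

## The toy genome

One chromosome (400 kb by default) carries:

* four multi-exon genes with alternative polyadenylation (18 kb span,
  four 1.5 kb internal exons, a 3 kb terminal exon holding a 1.2 kb cUTR
  and a 600 bp aUTR),
* three intronless small genes (ISGs; 5 kb, 400 bp cUTR, 300 bp aUTR),
* three single-poly(A)-site genes (the RUD background controls),
* LINE-1 copies — two full-length (6.5 kb, the ≥ 6 kb class), two
  5′-truncated fragments, one intronic fragment — plus SINE and LTR copies
  both intergenic and intronic,
* one duplicated 6 kb segment (source and identical copy) containing a
  2 kb LINE-1 fragment: reads from either side receive two equally scoring
  alignments and become the non-unique fraction.

Genes alternate strands; intergenic gaps of 10 kb keep the 4 kb downstream
extension windows clear of neighbouring gene bodies. Repeat copies are
derived from per-class consensus sequences at 20 % substitution
divergence; the consensus library is also the reference for attributing
unmapped reads. Requesting features that cannot fit raises a sizing error
naming the first unplaceable feature.

## Read generation

Each read picks a source: LINE-1 (rate λ; a 20 % sub-share is drawn from
the LINE-1 consensus itself, standing in for diverged expressed copies
absent from the assembly and therefore unmappable), SINE (0.05), LTR
(0.05), background intergenic transcription (0.20), random junk (0.01,
the sequencing-artifact floor), and genes otherwise. Repeat copies are
chosen with probability proportional to their length (transcriptional
output scales with copy length); fragments are placed uniformly inside the
element. Background intergenic reads are sampled outside gene bodies,
extension windows and annotated repeats — in real data most intergenic
reads do not overlap uniquely mappable repeat copies, and this keeps the
repeat fold-change estimator interpretable.

Gene reads choose the distal isoform with probability f, read through the
chosen site with probability ρ by an exponential distance (mean 2 kb,
"several kilobases", capped at 10 kb), and are spliced except for a 15 %
pre-mRNA (unspliced) share that generates intron and exon–intron reads.
Fragment lengths are normal(500, 100) truncated to [100, 1000] bp and
truncated at transcript boundaries; fragment starts are uniform along the
(possibly extended) transcript. Sequencing error is off by default; an
optional uniform substitution rate (0.01 when enabled) produces nonzero
mismatch counts for score-gap testing.

Truth records label every read with source, isoform, read-through flag and
exact genomic blocks. `emit_truth_psl` converts truth to 21-column PSL,
adding a second line at mirrored coordinates for placements inside a
duplicated segment, so uniqueness resolution can be exercised without an
aligner. A brute-force ungapped toy aligner (≥ 90 % identity, ≤ 1 Mb
genomes) exists for fixtures only.

Default condition contrasts: ρ 0.1 → 0.5, f 0.3 → 0.5, λ 0.02 → 0.04.
The default pipeline run uses 12,000 reads per condition plus 3 × 5,000
replicate reads per condition for the RUD comparison — a deliberately
desk-scale problem size; recovery tests use 20,000–60,000 reads where
tighter tolerances require it.

## Estimators and their numerical behaviour

**Uniqueness.** Score = matches − mismatches; unique iff the best hit
beats the second best by ≥ gap (default 10, boundary inclusive). Ties at
the top are never unique for positive gaps; the reported best hit breaks
ties by (chrom, start) for determinism. Reads present in the FASTA but
absent from the PSL are unmapped.

**Region classification.** Precedence exon > exon & intron > intron >
utr3_ext > utr5_ext > intergenic, with gene-body categories dominating
extension windows (the categories are mutually exclusive; the published
pie-chart convention does not state a tie rule, so this is a declared
choice). "Exon" requires every aligned base inside exons of a single gene;
"intron" accepts the union of introns across genes; extension windows are
anchored at the annotated transcript ends. Gene attribution ties break by
most overlapped bases, then lexicographic id.

**RUD.** The published score was microarray-based (the original
probe-level method is not specified in the source analysis); this package
defines a read-coverage analog. Known bias: because isoforms are chosen
per read and fragment starts are uniform per transcript, per-base coverage
density scales inversely with transcript length, depressing RUD by about
`f(1−f)·ΔL/L` where ΔL/L is the aUTR share of the transcript (≈ 0.015–0.03
for the default geometry). This is why default aUTRs are short relative to
their transcripts; the recovery tolerance (|mean RUD − f| ≤ 0.05) holds
with margin. Background is the mean coverage in 4 kb windows downstream of
single-site genes and is subtracted from both numerator and denominator;
RUD is undefined (flagged, excluded from sample means) when cUTR signal
does not exceed background. Replicate sample means are compared with
Welch's t test (the unequal-variance form, since only "t test" is
conventional here).

**Read-through index.** Upstream window: 500 bp ending at the proximal
site (covered by all isoforms, so the denominator does not depend on f);
downstream window: 500 bp starting 500 bp past the terminal site. These
emulate qRT-PCR amplicon placement. Ratios are undefined when upstream
coverage is zero; normalized folds divide by the reference condition's
per-gene ratio.

**Repeats.** Attribution threshold is ≥ 1 bp overlap; a read overlapping
two classes counts once in each class and is flagged (the per-class panels
are independent). Non-unique reads are attributed via the union of all
reported placements. The full-length criterion applies to the genomic
element length (≥ 6 kb), not the aligned span, and partial overlap
qualifies. 3′-end binning uses the alignment-strand-aware 3′-most base,
element-relative in 5′→3′ orientation, bin = ⌊5·pos/L⌋ with the element
end clamped into the last bin. Consensus matching for unmapped reads is
ungapped, both strands, best class when ≥ 50 % of the read aligns at
≥ 80 % identity — declared defaults, since no method is conventional for
this step.

**Fold changes.** Fold = ratio of within-category proportions. Because
the category total itself contains the repeat reads, doubling λ yields an
expected fold slightly below 2 (≈ 1.9 at the default rates); the recovery
test averages five replicate simulation pairs to separate this small
structural bias from sampling noise.

**Statistics.** Fisher's exact test sums hypergeometric probabilities
≤ the observed table's (minimum-likelihood two-sided convention, with a
1e−9 relative slack for floating-point ties; two-sided because the source
analysis does not state a convention). Chi-squared is Pearson's without
continuity correction; zero-margin columns are dropped with df reduced and
small expected counts flagged. The K-S P value is the asymptotic
Kolmogorov form at effective n = n₁n₂/(n₁+n₂), appropriate at the
hundreds-to-thousands-of-genes scale where it is applied (calibration is
verified at n = 500 per sample). Proportion SDs use √[p(1−p)/N].

**Stratification.** Gene length is the genomic span (switchable), the
short cutoff is the lower-tail-inclusive 20 % quantile with linear
interpolation, and the pseudo-signal added before log2 ratios defaults to
1.0 expression unit. The expression generator draws four gene groups
(2,130 long multi-exon, 300 short multi-exon, 250 short single-exon, 70
long single-exon — roughly one-fifth the scale of a full annotation, with
short genes ≈ 20 % of the total), log-normal baseline expression, 0.4
log2-SD condition noise, and a 0.5× factor on short single-exon genes in
the second condition.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis assumes:
condition-dependent read-through, distal-site usage and LINE-1 rates;
multi-hit alignments from exact duplications; unmappable repeat-derived
reads; unstranded ~500 bp fragments. It does not model sequencing-error
profiles (no homopolymer or indel errors), cell-type composition changes,
isoform diversity beyond two poly(A) sites per gene, inexact segmental
duplications, or expression heterogeneity across genes within a condition.
Passing recovery tests therefore demonstrates the estimators' correctness
under the stated model, not robustness to those real-data complications.
The published analysis's absolute numbers (mapping rates, microarray RUD
values, the 6,658 bp cutoff) depend on a specific read set and annotation
and are not reproduction targets; the pipeline's qualitative structure —
which categories shift, in which direction, and how strongly relative to
the dials — is.

## Degenerate inputs and determinism

Empty hit sets require an explicit read list (classified unmapped);
identical-score best hits are non-unique; empty region tables and
zero-exon controls raise errors; categories absent in both conditions
report P = 1 flagged; zero reference counts give flagged infinite folds;
all-undefined RUD samples raise; zero within-group variance in the t test
is flagged with P ∈ {0, 1}. All randomness flows from
`numpy.random.default_rng` seeds derived from a single pipeline seed via
`SeedSequence`; rerunning with the same configuration and seed reproduces
byte-identical report tables, which the test suite asserts.
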