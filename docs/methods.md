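# Methods

This note records the models behind `bsakit`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data do and
do not establish about real sequencing data.

## Cross and genome model

The genome defaults to the sixteen nuclear chromosomes of the S288c
reference (12.07 Mb total), the coordinate system yeast resequencing data
are mapped against. Recombination is uniform at 0.35 cM/kb — the yeast
genome-wide average — with crossover counts Poisson-distributed per
chromosome (mean = genetic length in Morgans) and breakpoints uniform, so
there is no crossover interference and two-point recombination follows
Haldane's mapping function c = (1 − e^(−2d))/2. No genetic map for the
mapped strain exists, so the standard neutral choice is used. Tetrad
structure (spore viability, gene conversion) is not modeled; segregants
are independent meiotic products.

Marker sites are placed uniformly over the genome (hence
length-proportional per chromosome), unique and sorted; the parent is
heterozygous at every marker. A realistic default marker count is ~18,000,
matching the density of a filtered heterozygous-site map in a heterozygous
wine strain; the default pipeline configuration thins this to 2,000
markers, which keeps the full run under a couple of minutes on one CPU
while leaving the marker spacing (~6 kb) far below the width of a support
interval (tens of kb), so interval calling is unaffected.

## Phenotype model

Resistance is a deterministic two-locus epistatic rule: haplotype A at the
major locus → Sensitive; haplotype B at the major locus → resistant, split
by the modifier locus into Resistant-Evolved (B at both) and
Resistant-Parental (B at major only). Each resistant-genotype segregant is
independently relabeled Intermediate with probability
`intermediate_fraction` (default 0.4). This is one plausible generating
model for a four-class phenotype distribution with roughly 1/2 sensitive
segregants and an intermediate class of ~20%; how intermediate clones
relate genetically to the two loci in real data is unknown, and the noise
class here is a modeling choice, not a claim. Intermediates are never
pooled — only the sensitive and the two resistant classes are sequenced.

## Sequencing model

Pooled read counts per site: true pool frequency f = mean genotype over
pool members; depth ~ Poisson(mean depth); alternate reads ~
Binomial(depth, f(1−ε) + (1−f)ε) with read-error rate ε = 0.002 by
default, a typical short-read substitution rate. Default pool depth is
80×, bracketing the 66–133× range of the study design this emulates.
Coverage tracks draw each window's summed base coverage as
Poisson(mean depth × copy/ploidy × window length). Expression counts are
negative binomial via a gamma–Poisson mixture with dispersion α
(var = μ + αμ², α = 0.05 default; α = 0 degenerates to Poisson), baseline
means log-uniform over ~10–3,000 counts, and a 3-parent / 1-evolved
replicate design.

What the generator does **not** emulate: GC and mappability bias in
coverage, index hopping or contamination between pools, base-level errors
correlated along reads, segmental CNV breakpoints mid-chromosome (planted
changes are whole-chromosome), and linkage between marker ascertainment
and the trait. Tests passing on these simulations therefore establish the
correctness of the statistics and interval logic under the stated
sampling models, not robustness to alignment artifacts or bias in real
libraries.

## LOD statistic and interval calling

The association score is the absolute log10 odds ratio of the two pools'
allele frequencies at a marker, computed from read counts with the
Haldane–Anscombe ½ continuity correction. Three conventions were open and
are fixed as follows:

* **½ correction** — keeps every site finite (complete selection at depth
  d scores ≈ 2·log10(2d+1), e.g. ≈ 3.8 at 40×), rather than dropping
  zero-count sites.
* **Absolute value** — the scan is two-sided and symmetric under swapping
  pools and under a simultaneous ref/alt swap.
* **Counts, not rounded frequencies** — retains depth information; a
  50/50 site at 20× and at 200× both give LOD 0, but divergence is
  damped at low depth, as it should be.

Peaks are markers exceeding LOD 3 that are maximal within their interval;
the support interval extends to the first marker on each side whose LOD
has dropped ≥ 1 unit below the peak (clamped to the chromosome's terminal
markers), endpoints reported at marker positions — the data's resolution.
Among equal-LOD candidates the leftmost wins, and overlapping intervals on
a chromosome are merged keeping the higher peak, so output is
deterministic. No smoothing is applied by default (the score is reported
per variant); a centered rolling median over k sites is available for
noisy low-depth tracks.

Detection limits worth knowing: a fixed-versus-0.5 contrast (e.g. the
modifier locus against the sensitive pool) is capped near
log10(2d+1) ≈ 2.2 at 80×, below the LOD-3 cutoff — deep pools are needed
before such loci cross the threshold — while fixed-opposite contrasts
(≈ 4.4 at 80×) are called comfortably. Conversely, pools of ~9 segregants
are small enough that genetic drift occasionally fixes an unlinked region
in one pool and produces a spurious LOD-3 peak in a 9-vs-9 comparison
(observed in roughly 8% of simulated replicates); the 37-member sensitive
pool suppresses this in the sensitive-vs-resistant comparisons, which is
where the major-locus recovery is assessed (≥90% of replicates contain
the planted position in both comparisons' intervals, with no null-
chromosome calls observed).

## Copy-number scan

Windows are non-overlapping 1000-bp tiles (a stride option provides
sliding windows); the final partial window is averaged over its true
length, and positions absent from the depth table count as zero coverage.
Chromosome ratios use medians (chromosome median window depth over
genome-wide median), robust to segmental CNV and invariant under global
depth scaling. A chromosome is flagged aneuploid when its ratio lies
within ±0.15 of k/ploidy for the nearest integer k ≠ ploidy; 0.15 keeps
the diploid band [0.85, 1.15] disjoint from the trisomy band
[1.35, 1.65] at any realistic window count. Runs of ≥10 consecutive
off-band windows are additionally reported as putative segmental CNVs —
an extension beyond the chromosome-level calls, labeled as such.

## Expression dosage

Size factors are median-of-ratios over genes with nonzero counts in every
sample; fold changes are log2 of the ratio of normalized strain means with
a 0.5 pseudocount (stabilizes low counts and makes all-zero genes score
exactly 0). Differential-expression testing is intentionally out of
scope: the binning step accepts externally computed significance flags
(e.g. FDR < 0.05 from a count-model test) and otherwise runs
descriptively over all genes; the dosage summary reports both all-gene
and significant-only means, since which of the two a published summary
used is often ambiguous. "Two-fold or greater" is inclusive
(|log2 FC| ≥ 1).

A known small-sample property: with a single evolved replicate and
α = 0.05, E[log X] < log E[X] (Jensen), which shifts all fold changes
down by ≈ 0.03–0.05 log2 units relative to the truth — the dosage
chromosome's mean lands near 0.54 rather than 0.585, and the complement
near −0.04 rather than 0. The effect shrinks with replicates and grows
with the aneuploid chromosome's share of the transcriptome (the
size-factor median absorbs part of the excess once that share is more
than a few percent). This is a property of the estimator under the
study's replicate design, not a bug; both values remain within the
recovery tolerances used in the tests.

## Pipeline

One global integer seed is fanned out to per-stage streams through
`numpy.random.SeedSequence([seed, stage])`, so stages are independently
reproducible and a rerun with the same config is byte-identical (the
manifest records SHA-256 checksums of every artifact; nothing
time-stamped is written). Phenotype-class percentages are rounded to the
nearest integer. Thresholds are validated at config construction; a stage
failure aborts the run with the stage named.

## Degenerate inputs and tie-breaks

* Zero-depth sites in a scan are skipped with a logged count, not an
  error; an empty pool, an empty marker join, or a missing sample is an
  error naming the offender.
* Multiallelic VCF records are skipped with a logged count.
* De-novo matching requires the identical alternate allele, not just the
  position — the stricter reading of "same variant".
* Heterozygous-site filter bounds are inclusive on both ends so the
  printed limits (0.25, 0.75, 20 reads) are attainable.
* BED output is 0-based half-open; all internal coordinates are 1-based
  closed (VCF convention).
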