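# bsakit

Bulk-segregant QTL mapping, read-depth aneuploidy detection and
chromosome-dosage expression analysis for yeast crosses — with a fully
seeded synthetic cross generator, so the whole pipeline can be exercised
and validated without any raw sequencing data.

## The problem

A diploid wine yeast heterozygous at thousands of sites is sporulated;
haploid monosporic clones segregate a resistance trait (here: growth on
molybdate, a toxic sulfate analogue) into phenotype classes. Pools of
phenotyped segregants are sequenced, and a locus affecting the trait
reveals itself as a site where the pools' allele frequencies diverge.
`bsakit` implements that mapping workflow end to end:

1. **Marker calling** — parent-heterozygous sites are taken as markers,
   filtered to allele frequency within [0.25, 0.75] and depth ≥ 20 reads
   (bounds inclusive).
2. **LOD scan** — each marker is scored across a pool pair with the
   absolute log10 odds ratio of the pooled allele frequencies, computed
   from read counts with the Haldane–Anscombe ½ correction:

       LOD = | log10( ((a_alt+½)/(a_ref+½)) / ((b_alt+½)/(b_ref+½)) ) |

   Peaks with LOD > 3 are called as QTL; each peak's support interval runs
   to the first flanking marker whose LOD has dropped 1 unit below the
   peak, and intervals from independent pool comparisons are intersected
   into a common region.
3. **Copy-number scan** — sequencing coverage is averaged in 1000-bp
   windows; each chromosome's median window depth is divided by the
   genome-wide median, and ratios sitting on a non-baseline copy-number
   grid point are flagged (a trisomic chromosome in a diploid shows a
   3:2 = 1.5× ratio).
4. **De-novo variants** — evolved-strain calls minus everything present in
   the parent (same chromosome, position, and alternate allele) or
   heterozygous in the parent.
5. **Expression dosage** — median-of-ratios normalization, per-gene
   log2 fold changes, per-chromosome mean fold change against the rest of
   the genome (a chromosome at 1.5× dosage is expected near
   log2 1.5 ≈ 0.585), and up/down × two-fold binning of significant genes.

The synthetic generator simulates the matching data: Poisson crossovers
without interference (Haldane's mapping function c = (1 − e^(−2d))/2),
a deterministic two-locus epistatic phenotype rule with an Intermediate
noise class, Poisson site depths with binomial allele sampling and a
symmetric read-error rate, Poisson window coverage scaled by planted copy
numbers, and negative-binomial expression counts with chromosome dosage
folds.

## Worked example

Run the default simulated study — a 69-segregant cross with an 18k-site
marker map thinned to 2,000 markers, three sequenced phenotype pools at
80×, a major locus on chrXII (543.5 kb) with a chrIV modifier (471.5 kb),
chrI planted at three copies, and a 1.5× chrI expression dosage:

```sh
bsakit run --seed 1 --outdir demo
```

Selected output (files under `demo/`):

* `cluster_report.json` — 69 segregants split 40 Sensitive / 7
  Resistant-Parental / 12 Resistant-Evolved / 10 Intermediate (58% of this
  draw's clones are sensitive; intermediates are never pooled).
* `qtl_intervals.bed` — both sensitive-vs-resistant comparisons call
  chrXII:532,355–570,876 (containing the planted 543.5 kb locus), and the
  resistant-vs-resistant comparison calls chrIV:462,236–488,499
  (containing the planted modifier); `common_region.bed` holds their
  cross-comparison intersection.
* `aneuploidy.tsv` — chrI depth ratio 1.5000, copy estimate 3, flagged;
  all other chromosomes sit at ratio ≈ 1.0, copy 2.
* `dosage_summary.tsv` — chrI (104 genes this draw) mean log2 FC 0.43
  versus −0.04 for the rest of the genome: the dosage signature of the
  extra chromosome copy, shrunk slightly below log2 1.5 by the
  single-replicate fold-change noise (see `docs/methods.md`).

Every stage is also callable on its own (`bsakit simulate cross`,
`bsakit filter-het`, `bsakit bsa-scan`, `bsakit cnv-scan`,
`bsakit denovo`, `bsakit expr-dosage`) or as plain library functions; the
manifest records parameters, seeds and SHA-256 checksums, and a rerun with
the same config is byte-identical.

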