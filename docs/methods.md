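# Methods

This note documents the models and procedures panelmap implements, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions used throughout.

## Coordinates and file formats

All coordinates are 1-based inclusive internally, the VCF/GFF convention;
BED's 0-based half-open convention is applied only when writing BED.
FASTA is read through Biopython, VCF through pysam and GFF3 through
gffutils; sequences are uppercased, with soft-masking discarded and
non-ACGTN IUPAC codes mapped to N. VCF records that are multiallelic or
non-SNP are dropped (and tallied), not split: the panel rules and the ED
statistic are defined on biallelic SNPs, and splitting would manufacture
sites the filters were never meant to see. Half-called genotypes count as
missing.

## Panel-design cascade

A candidate SNP survives four rules, applied as pure per-site predicates
(so the survivor set is independent of evaluation order, which the test
suite checks by permuting the cascade):

1. **MAF/missingness.** Minor-allele frequency is computed from allele
   counts over called diploid genotypes; a site is kept iff MAF ≥ 0.05
   (boundary inclusive, matching a threshold stated as a value) and
   missing rate < 0.50 (boundary exclusive, matching a rule stated as
   "less than"). A site missing in exactly half the cohort is rejected.
2. **Flanks.** The 100 bp upstream and downstream of the site must lie
   fully inside the chromosome (probes need complete context), contain no
   N, and each flank independently must have GC strictly inside
   (0.40, 0.60). N bases are excluded from the GC denominator — moot once
   the no-N rule has fired, but defined for robustness.
3. **Single copy.** The 201-bp probe context (flank + SNP + flank) must
   not align anywhere else over ≥ 120 bp (60% of the probe). The built-in
   search indexes genome k-mers (k = 31), samples every k-th probe k-mer,
   and extends each seed to its maximal exact run on both strands. Any
   exact duplicate of length ≥ 2k−1 = 61 bp shares a sampled seed, so
   completeness is guaranteed for exact matches at the 120-bp rule.
   Diverged (inexact) homologies are outside this guarantee; for
   production genomes an adapter accepts hit tables from an external
   aligner (e.g. BLAST tabular output) instead.
4. **Functional class.** Survivors are classified against the annotation:
   intergenic, noncoding_genic, or — inside a CDS — synonymous /
   nonsynonymous / start_codon_change / stop_codon_change by strand-aware
   codon translation under the standard genetic code. Each gene uses its
   longest mRNA's CDS chain; the first codon is taken as the start codon.
   Genes whose CDS chain is frame-inconsistent fall back to
   noncoding_genic with a warning.

Rejections are tallied under the first failing rule, so
survivors + tallies = inputs exactly. The published array's final
down-sampling rule (from filter survivors to the synthesized marker count)
is not stated anywhere we could find; `thin_panel` provides an explicit
greedy minimum-spacing stand-in, default off. Density reporting uses 1-Mb
bins by default (typical chromosome-density-plot resolution; configurable).

## BSA-seq ED statistic

At each SNP informative between the two bulks (pool genotype calls differ
and both carry allele depths), the ref/alt depths are projected onto the
A/C/G/T axes at the ref and alt bases and normalised to base frequencies.
The statistic is ED = √Σ_b (p1_b − p2_b)², in [0, √2] for biallelic sites,
raised to a power k (default 2, the "correlation value"; classic ED
pipelines use up to 5) to suppress background noise. Squaring is monotone,
so site rankings are unchanged.

**SNPNUM fit.** The ED^k profile is smoothed per chromosome with a median
over a window of a fixed *count* of SNPs (default 101, step 1), never
spanning chromosome boundaries. Near chromosome ends the window shrinks
symmetrically; a window at least as large as the chromosome's site count
collapses to the whole-chromosome median. The median (rather than a mean)
makes the fit robust to isolated high-ED sites. The source methodology
names the SNP-count windowing without printing its parameters; 101 SNPs is
this package's documented default.

**Threshold and intervals.** No threshold rule is printed in the source
methodology either; the default here is genome-wide median + 3·SD of the
fitted values, with an empirical-quantile alternative. Candidate intervals
are maximal runs of consecutive sites strictly above threshold, with runs
separated by fewer than `gap_sites` (default 2) low sites merged and runs
of fewer than `min_sites` (default 5) above-threshold sites discarded.
Sites with total pool depth below 10 in either pool are excluded before
fitting (frequency-noise control). Interval length is end − start + 1,
reported in Mb at one decimal.

## F2 statistics

FSI descriptives use sample SD (n−1), divisor-n central moments for skew
(g1 = m3/m2^1.5) and excess kurtosis (g2 = m4/m2² − 3), and
CV% = 100·sd/mean; small-sample bias-corrected G1/G2 are available behind
a flag. Shape classification is oval iff FSI > 1.0 (the boundary goes to
round). The segregation test is the uncorrected χ² against expected
(¾n, ¼n) with one degree of freedom and critical value 3.841; Yates
correction is deliberately not applied — on the 1084:351 reference count
table the uncorrected statistic reproduces the published 0.22 while the
corrected one gives ≈0.20. qPCR fold changes use
2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_calibrator.

## Fine mapping

Under one locus with the maternal allele dominant, a recessive-class
individual must be homozygous paternal (B) at the causal position and a
dominant-class individual must not be B there; heterozygous or
maternal-homozygous genotypes of dominant individuals are uninformative
because dominance masks Aa vs AA. Recombinants are individuals whose
genotype class changes between consecutive non-missing markers; each
change is localised to the physical interval between those markers.
Individuals with two or more breakpoints (likely genotyping errors) are
excluded by default, with an override.

Narrowing evaluates *candidate elements*: every marker position and every
open interval between adjacent markers. A marker is compatible with a
record when the genotype there satisfies the phenotype constraint; a gap
is compatible when either flanking marker is, because a single crossover
inside the gap can carry the causal genotype even when one flank excludes
it. The causal locus generally sits strictly between markers, so pure
marker-point consistency would wrongly declare informative crosses
unsolvable — the gap elements are what make the narrowing sound. The
reported interval runs between the nearest fully excluded marker on each
side of the consistent block, falling back to the enclosing BSA interval
(or the map ends) on a side with no exclusion. Interval length is
end − start + 1 bp, with kb rounded to one decimal; for the reference
flanking coordinates (81 539 936, 82 252 537) both the inclusive and the
difference convention round to 712.6 kb.

An empty consistent set raises an error listing the conflicting
individuals rather than guessing: with noisy phenotypes (see below) a
strict one-locus model can genuinely be violated, and silently dropping
records would hide that.

Gene listing uses the any-overlap rule by default (a gene straddling an
interval edge is a candidate; "fully contained" is available). W-box
scanning reports 1-based forward-coordinate start positions on both
strands for the degenerate consensus [CT]TGAC[TC], the exact literal
TTGACC, and the conserved TGAC core, all overlapping occurrences included.
Allele diffing globally aligns the two sequences (match +1, mismatch −1,
affine gaps −2.5/−0.5 — gap opening is penalised enough that a clean
deletion aligns as one block) and reports SNPs and contiguous indels with
positions on the first sequence.

## Synthetic data

The generators emulate the study conditions the toolkit is built for: a
population of a few dozen to a few hundred accessions genotyped at
biallelic SNPs, and an F2 mapping population of 1435 individuals
segregating a single dominant fruit-shape locus, with 30 + 30
extreme-phenotype bulks sequenced to ~30×.

* **Genomes** are uniform-random A/C/G/T with requested features planted
  verbatim: duplicated blocks (for the single-copy rule), N runs, and
  GC-extreme windows (bases redrawn at the requested GC probability).
  Planted features must not overlap. At desk scale (tens to hundreds of
  kb) a random genome essentially never contains an accidental ≥120-bp
  repeat, so planted duplicates are the only copies.
* **Population genotypes** come in two modes. *Construction* mode sets
  genotype counts deterministically to hit an exact MAF and missing rate —
  each violation site fails exactly one rule, giving a truth table the
  cascade must reproduce site for site with no sampling noise. *Sampling*
  mode draws Hardy–Weinberg genotypes at a true allele frequency for
  statistical calibration. Clean-site placement verifies flank GC/N purity
  against the actual genome with the generator's own local checks.
* **F2 crosses** simulate two independent F1 gametes per individual over
  the marker map under a Haldane (no-interference) model at 1 cM/Mb — the
  simplest defensible map for desk-scale tests. The phenotype model is
  FSI ~ N(1.2, σ) with at least one maternal allele at the causal locus
  and N(0.9, σ) otherwise; σ defaults to 0.04, the oval parent's reported
  SD. The F2-wide FSI SD then emerges from the genotype mixture rather
  than being forced. Note the deliberate consequence: at σ = 0.04 about
  0.6% of recessive individuals exceed the FSI = 1 boundary and are
  misclassified, which is realistic for a ratio trait measured once — the
  3:1 χ² absorbs it, pool construction from the distribution tails is
  insensitive to it, but strict fine-map narrowing is not, so
  fine-mapping fixtures use a smaller σ (reliable phenotype scoring of
  the genotyped recombinants, as a real fine-mapping study would ensure).
* **Pools** take the n lowest- and n highest-FSI individuals, draw
  Poisson read depth per site and binomial maternal-allele reads at the
  pool's true maternal frequency, and emit per-base depth tables. At the
  causal locus the oval (dominant) pool's expected maternal frequency is
  2/3 (1 AA : 2 Aa among dominants) against ~0 in the recessive pool,
  giving ED² ≈ 0.89 against a background of ~0.05 at 30×.

What the generators do *not* emulate: linkage disequilibrium and
population structure of a real germplasm panel, crossover interference,
segregation distortion, read-level sequencing artefacts (mapping bias,
base errors), multi-locus or polygenic architecture of the trait. Passing
tests therefore demonstrate that the algorithms are implemented correctly
under their stated models, not that those models capture every property of
real resequencing data.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at the study's scale where that is what the
check is about — 1435-line crosses, 30 + 30 pools at ~30×, 2000 genome-wide
markers, 100 seeded replicates for locus recovery, 10 000 draws for χ²
type-I calibration, 1000-site construction-mode panels — and at smaller
sizes (hundreds of individuals, tens of kb of genome) for unit-level
oracle comparisons where scale adds nothing. All generators are
bit-reproducible under a fixed seed.

## Known limitations

* The built-in copy search guarantees only exact-match completeness;
  diverged repeats need an external aligner via the hit-table adapter.
* The SNPNUM window size, ED threshold rule and pool depth floor are this
  package's documented defaults, not published values; conclusions that
  depend on them should be checked across settings.
* Interval narrowing assumes a fully penetrant single dominant locus;
  phenotype misclassification or a second linked locus produces an
  inconsistency error rather than a (possibly wrong) interval.
* The VCF writer emits the minimal GT/AD subset the toolkit itself
  consumes; it is not a general-purpose VCF emitter.
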