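# Methods

## Overview

`niptkmer` detects fetal autosomal trisomies from low-coverage whole-genome
cfDNA sequencing without mapping reads. The method rests on a simple idea:
if each chromosome is represented by a fixed list of k-mers that occur
exactly once in the genome and behave stably across individuals, then the
number of list k-mers observed in a sample's raw reads is a direct proxy for
that chromosome's sequencing coverage, and a trisomic chromosome shows a
small but systematic excess.

The pipeline has three stages:

1. **List building** — per-chromosome unique k-mer lists, filtered for
   polymorphisms, problematic regions and population stability.
2. **Counting** — intersect a sample's raw-read k-mers with each list,
   yielding per-chromosome counts `K_sc` and the sample GC fraction `GC_S`.
3. **Calling** — a linear-regression coverage model, one-sided z-scores for
   trisomy, four sex-chromosome models for fetal sex, and a Mahalanobis
   distance for sample-level QC.

## Canonical k-mers

All matching is strand-collapsed: a k-mer is stored as the lexicographic
minimum of itself and its reverse complement, because sequencing reads come
from either strand. K-mers are packed 2 bits/base into `uint64` codes;
A<C<G<T maps to 0<1<2<3, so numeric order on codes equals lexicographic
order on strings, and one sorted code array serves for set algebra, file
output, and binary-search lookups alike. This bounds k at 32; the default,
k = 25, balances specificity (uniqueness genome-wide) against robustness to
sequencing errors — longer k-mers are more often broken by an error, shorter
ones are less often unique. Windows containing any non-ACGT symbol are
skipped (the window, not the whole read); lowercase (soft-masked) sequence
is treated as ordinary sequence — hard exclusion is the region filter's job.

Counting is exact and in-memory (hash/sort based, no probabilistic
sketches). This is sized for toy-scale validation and moderate genomes; a
full human-genome run would need the same algorithms in a disk-backed
implementation, which is out of scope here.

## List building

For each chromosome the initial list holds every canonical k-mer of the
reference sequence with its count. Four filters follow:

* **Uniqueness.** A k-mer is kept on chromosome c only if its genome-wide
  canonical count is exactly 1. This removes repeats within and across
  chromosomes (including pseudoautosomal sequence, which appears on both X
  and Y).
* **Polymorphisms.** For every variant with minor-allele frequency ≥ 1%
  (default `maf_min=0.01`; records lacking a frequency field count as
  common, which errs toward exclusion), all k-mers of every haplotype over
  the variants inside the k−1-flanked window are removed — reference and
  alternate alleles alike, subtracted genome-wide, since an alt-allele k-mer
  may coincide with reference sequence elsewhere. Dense variant clusters
  whose allele combinations exceed `max_haplotypes` (default 4096) fall back
  to removing all reference k-mers of the window. Indels are substituted as
  allele strings; the flanks preserve k−1 context.
* **Excluded regions.** Every k-mer whose window overlaps a BED interval by
  ≥ 1 base is removed (low-complexity runs, telomere/centromere analogues,
  pseudoautosomal regions). Coordinates: BED 0-based half-open, VCF 1-based;
  internally 0-based half-open.
* **Population stability.** For each deep-coverage control individual
  (20–30x), a k-mer's count is modelled as Poisson with mean λ equal to the
  control's average per-k-mer coverage. Counts outside the central interval
  [smallest x with CDF(x;λ) ≥ 0.01, smallest x with CDF(x;λ) ≥ 0.99]
  (inclusive at both ends) indicate the k-mer is not present in exactly two
  copies in that genome, or sits in a region with systematic sequencing
  bias; such k-mers are dropped. The final list is the intersection over all
  controls, so adding controls can only shrink a list.

**λ estimation.** λ defaults to the mean count of candidate k-mers present
in the control — controls are deep, so zero-truncation bias is negligible —
and is estimated *per chromosome*. This matters for sex chromosomes: in a
male control, X and Y are haploid, their k-mers count at ~λ/2, and a single
genome-wide λ would reject nearly all of them; a per-chromosome mean adapts
the interval to the actual copy number. A chromosome essentially absent from
a control (chrY in a female control: < 5% of candidates present or λ < 1)
contributes no stability constraint from that control; this is logged and
recorded in the manifest.

Each run emits one gzip text list per chromosome (header line, then
`kmer<TAB>count` sorted lexicographically) plus a JSON manifest carrying k,
per-chromosome list sizes `L_c`, the filter parameters, control identifiers,
and a SHA-256 content hash that downstream outputs cite for provenance.

## Counting

A sample's FASTQ (plain or gzip) is converted to a canonical k-mer count
list; windows never span read boundaries. Each k-mer is looked up in the
merged chromosome index (final lists are disjoint by construction, so
ownership is unique). Two count definitions are provided:

* `occurrences` (default): `K_sc` = summed sample counts of chromosome-c
  list k-mers. Proportional to depth at any coverage.
* `distinct`: number of list k-mers seen at least once. Saturates as depth
  grows; retained because at very low coverage the two are nearly identical
  and some workflows count presence.

`GC_S` is the G+C fraction over all called bases of all reads (N excluded
from numerator and denominator), computed stream-wide rather than averaged
per read.

The cohort matrix has one row per sample and one column per chromosome plus
`gc`; it round-trips losslessly through its TSV (`%.17g`, round-trip float
parsing) and carries the list manifest hash — a sample counted against
different lists cannot be stacked silently.

## Coverage model and calling

Per-chromosome coverage is `C_sc = K_sc / L_c`. Relative coverages vary
between samples with a consistent pattern (GC effects, library chemistry),
so each target chromosome gets its own ordinary least-squares model,
**without intercept**, fitted on declared euploid reference samples only:

    C'_sc = β₁C₁ + … + β_pC_p + β_GC·GC_S,    β̂ = (XᵀX)⁻¹Xᵀy.

Predictors for an autosome are the other autosomes plus GC; for X or Y, all
autosomes plus GC. Sex chromosomes are never predictors, keeping autosome
models independent of fetal sex. The absence of an intercept makes
predictions scale with overall depth, which is the dominant nuisance
variation in cfDNA cohorts (an optional intercept flag exists, default
off). The implementation solves via `numpy.linalg.lstsq` after a
conditioning check (cond > 1e10 → error advising more references); a fit
requires at least `p + 5` reference samples.

The normalized difference `D_sc = (C_sc − C'_sc)/C'_sc` (the *predicted*
coverage is the denominator) is standardized against the reference
population (sample SD, n−1):

    Z_sc = (D_sc − mean(D_ref)) / SD(D_ref).

A chromosome is called **elevated** iff `Z_sc > cutoff`, one-sided, strict
inequality, default 3.5. Under normality this cut-off has a one-sided
false-positive rate of ≈ 0.023% per chromosome, below the 0.05% design
bound. Only gains are called: monosomy and sex-chromosome aneuploidy are out
of scope. The cut-off is configurable because the z-score spread depends on
coverage, platform and population; each laboratory must calibrate it on its
own cohort.

**Expected signal.** If n% of cfDNA is fetal and the fetus carries a full
trisomy, the affected chromosome's relative coverage shift under the
maternal-fixed parametrization is `(100 + 3/2·n)/(100 + n) − 1 =
0.5·n/(100+n)` (≈ 4.5% at n = 10). The simulator uses the weight-based
definition (fetal reads are exactly n% of the total), for which the
expected elevation relative to the disomic autosomes is
`0.5·w·r/(1 − w + w·r)` with `w = n/100` and `r` the maternal/fetal
genome-length ratio — ≈ 0.5·n/100 when the trisomic chromosome is small
against the genome. Both parametrizations agree to first order in n; tests
hold each implementation to its own algebra.

## Fetal sex

Four models are fitted — X and Y targets, each on female-fetus and
male-fetus reference pregnancies separately — and a sample is assigned the
hypothesis minimizing `z_X² + z_Y²`. Sex scoring uses the absolute-residual
z `(C_obs − C')/SD_ref(C_obs − C')` rather than the relative difference,
because the female-hypothesis Y model predicts coverage ≈ 0, where a
relative difference is undefined. The residual SD is floored at 1e-3 times
the mean reference autosome coverage so that the degenerate
all-zero-Y-in-female-references case cannot amplify numerical dust into a
confident call. An exact score tie is reported as `ambiguous`, never
silently resolved.

## Mahalanobis QC

Sample-level quality is summarized as the Mahalanobis distance of the
vector (D_sc for every chromosome, raw GC_S) from the reference centroid,
with the covariance estimated on the reference set. Sex-chromosome D values
for this vector come from models fitted on all references (mixed sexes) —
the distance is a QC flag for atypical samples (aneuploidy, contamination,
GC anomalies), not a calling statistic, and is not thresholded by default.
A near-singular covariance (cond > 1e12) is ridge-regularized by
1e-8·trace/dim, logged; GC enters raw (unstandardized), which the
covariance absorbs.

## Synthetic data

The generator produces every input at toy scale, fully determined by one
seed (byte-identical files):

* **Genome** — four autosomes (150/130/110/90 kb), X (120 kb), Y (60 kb);
  per-chromosome GC target ~N(0.5, 0.04) so the GC regressor has signal;
  planted duplicated blocks (1% of each chromosome in 400 bp blocks)
  exercising the uniqueness filter; low-complexity tandem runs and a 1.5 kb
  X/Y-shared pseudoautosomal block, both emitted as exclusion-BED truth.
* **Variants** — SNVs at 1/800 bp with MAF uniform on [0.002, 0.5],
  deliberately straddling the 1% filter threshold.
* **Individuals** — two haplotypes per autosome (X/Y by sex), each variant
  carried with probability MAF per haplotype; children take one haplotype
  per chromosome from each parent; a trisomy adds a third copy from a random
  parent. An optional CNV plants a duplicated segment in a control.
* **Reads** — single-end, default 85 bp (the shorter-read regime is
  representable via `read_length=50`), uniform over all haplotype copies, so
  a trisomic chromosome carries 3/2 the read density; per-base substitution
  errors at 0.002; optional logistic GC acceptance bias (off by default).
  Controls are sequenced at 25x (emulating 20–30x population controls);
  cfDNA samples at a mean depth of 16x with per-sample depth drawn uniformly
  from ±25% of the mean. Two scalings are deliberate departures from real
  cfDNA numbers, both forced by the ~3-orders-of-magnitude shorter toy
  chromosomes: the absolute depth is raised so that per-chromosome counting
  noise (which scales as 1/√(reads per chromosome)) reaches the regime where
  a 10% fetal fraction trisomy separates at 3.5 SD, and the depth *spread*
  is kept because the no-intercept regression is identifiable only when
  common depth variation spans the design space — with every sample at
  identical depth the model amplifies noise instead of normalizing it.
* **cfDNA mixture** — maternal reads with weight (100−n)/100 and fetal with
  n/100 (weight-based fetal fraction), fetal sex and trisomy configurable.

Not emulated: cfDNA fragment-size distributions, PCR duplicates, platform
error profiles, mosaicism, real repeat families, population structure.
Passing tests therefore demonstrate the statistical machinery end-to-end
under controlled conditions; they do not certify performance on real
sequencing data, where list quality and laboratory-specific cut-off
calibration dominate.

## Numerical and testing choices

* Poisson quantiles use `scipy.stats.poisson.ppf` (smallest integer with
  CDF ≥ p), verified in tests against term-by-term pmf summation.
* The regression is cross-checked against an explicit normal-equation solve
  and against `statsmodels` OLS; reference z-scores are standardized exactly
  by construction and asserted so.
* Retention checks for the stability filter use a binomial SE with an
  effective sample size of n/(read_length − k + 1): counts of overlapping
  k-mers covered by the same read are correlated, and treating every k-mer
  as independent would understate the SE several-fold.
* Mean-shift concordance is measured as the trisomic-minus-euploid
  difference over held-out samples: a model fitted on finitely many
  references carries a small prediction offset common to all test samples,
  which the difference cancels exactly.
* Test problem sizes: the end-to-end cohort uses 60 references, 10 euploid
  and 5 trisomic tests on the default toy genome; shift concordance uses 50
  trisomic samples at reduced depth; the counting path is checked against a
  brute-force oracle on 1000 random read sets at k ∈ {5, 11, 25}.

## Known limitations

* In-memory counting: full human-genome lists (~10⁹ k-mers) exceed this
  implementation's intended scale.
* k ≤ 32 (2-bit packing in a 64-bit word).
* Fetal-fraction estimation, mosaicism-aware scoring, microdeletion/CNV
  detection, monosomy and sex-chromosome-aneuploidy calling are out of
  scope.
* The Poisson stability model assumes roughly uniform coverage within a
  chromosome; strong GC-coupled coverage waves in controls would widen the
  empirical count distribution beyond Poisson and over-prune lists.
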