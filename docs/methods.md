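# Methods

This note documents the models, estimators and numerical choices behind
`phenospace`, and what the synthetic study conditions do and do not
establish about real data.

## Synthetic study design

The generator emulates a common-garden comparison of a wild inbred
panel against F2 recombinants for a selfing species.

**Genotypes.** Ancestral allele frequencies are Uniform(0.05, 0.95);
per-group frequencies follow the Balding–Nichols model
Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target F<sub>ST</sub>
(default 0.2, three groups).  Accessions are fully homozygous draws
(dosage 2·Bernoulli(p)); 1,000 SNPs sit on five chromosomes of 1 Mb /
100 cM each with a uniform genetic map.

**Crosses.** The crossing design is balanced: the first n/2 crosses are
a random perfect pairing of the panel, further crosses are random
pairs.  This mirrors designed cross panels in which every accession is
a parent; with independent random pairs a sixth of the panel is never
crossed and its trait-space neighbourhood goes unexplored by the F2s,
which distorts outlier detection.  Each F1 is deterministic; F2s are
unions of two independent F1 gametes with Poisson crossover counts per
chromosome and uniform crossover positions in cM (Haldane model, no
interference).  Default: 160 crosses × 4 offspring = 640 F2s, i.e. the
emulated study's scale divided by roughly four to keep the full
pipeline fast on one CPU.

**Traits.** Six additive polygenic traits with disjoint causal sets and
allele coding a(dosage − 1), so the F1 sits at the parental midpoint.
Regimes:

- *divergent* (flowering time, biomass): effects solved by minimum-norm
  least squares so expected group means equal the optima (defaults
  ±0.6 and ±0.45 SD — chosen so default Q<sub>ST</sub> falls in the
  range reported for real panels, roughly 0.2–0.45, and the F2 cloud
  still covers the accessions except at the margins), plus a random
  null-space component for polygenicity.
- *stabilizing* (SLA, LDMC, LNC): causal loci are drawn among loci
  polymorphic in the realized panel (MAF ≥ 0.1) with small among-group
  frequency spread; effects lie in the lowest-variance directions of
  the realized accession genotype matrix, constrained orthogonal to
  group-mean differences.  Group means then coincide exactly and the
  panel's genetic variance is a small fraction of the
  linkage-equilibrium variance Σ4p(1−p)a² — the "complementary +/−
  configurations" that recombination releases as transgression.  The
  `effect_sd` parameter sets the releasable (LE) standard deviation.
- *neutral* (leaf area): iid Gaussian effects; among-group variance
  arises from drift alone.

**Phenotypes.** value = baseline (20 trait units, keeping log/sqrt
transforms defined) + genetic value + additive block effect + Gaussian
residual with Ve = Vg(1−h2)/h2, Vg the *realized* genetic variance over
all genotypes, so h2 = 1 gives exact equality of phenotype and genetic
value.  Accessions are replicated once per block (three blocks); F2s
are unreplicated in a random block.  Missingness is completely at
random (default 8% on LNC only).  Planted outliers add
`shift_sd` × (accession-level phenotypic SD) to one trait of randomly
chosen accessions and overwrite a 50 kb haplotype block on chromosome 1
with the minor allele.

**What the generator does not emulate:** linkage disequilibrium beyond
the planted haplotype block, dominance and epistasis, selection during
the simulated generations, realistic site-frequency spectra or
recombination maps, genotype-by-environment interaction, and
non-random missingness.  Passing tests therefore establish that the
estimators recover *these* effects under additive, MCAR, LD-free
conditions — not that real panels satisfy those conditions.

## Preprocessing

Block effects are least-square estimates from the replicated accessions
(fixed-effects fit value ~ genotype + block; unbalanced data and
missing cells allowed), expressed as deviations of blocks 2+ from
block 1 and subtracted from both generations.  Correction operates on
raw trait values; transforms (log10 for flowering time and SLA, square
root for LNC and biomass) come next, then per-accession averaging over
replicates (missing replicates ignored), then optional imputation, then
standardization (mean 0, SD 1, n−1 denominator).  Imputation is
regularized iterative PCA (EM with truncated SVD, rank 2 by default,
missing cells initialized at column means, observed cells never
altered); rank 2 was chosen as the smallest rank that captures the
group-structure signal shared across traits.

## Hypervolumes

Boundary: one-class SVM with RBF kernel, ν = 0.01.  The kernel width
defaults to γ = 6d / Σ<sub>j</sub> range<sub>j</sub>² — scale- and
translation-invariant, calibrated once against closed-form volumes of
uniform boxes in d = 2, 3, 5 (errors within ~15%).  A fixed γ cannot
serve both dense low-dimensional clouds and sparse 500-point clouds in
five dimensions: small values over-smooth (a unit square inflates to
~1.35), large values fragment sparse clouds into disjoint islands.

Volume: Monte-Carlo with uniform candidates in the bounding box
expanded by 0.5 × range per side (default 500 candidates per data
point); accepted candidates are kept as the interior cloud, whose
density ρ defines the inclusion radius ρ^(−1/d) (boundary ties count
as included).  Intersection of two hypervolumes is estimated
symmetrically (average of the two directional cloud-classification
estimates) and clipped to min(vol<sub>A</sub>, vol<sub>B</sub>).
Group comparisons resample both groups to equal size without
replacement (per-rep seeds derived from the master seed by counter) and
report the mean and SE of volumes.

PCA axes are tested by a sequential permutation procedure: axis k is
significant if its eigenvalue exceeds the (1 − α/k) quantile of k-th
eigenvalues of column-permuted data, testing until the first failure.
On synthetic data the six traits are near-independent by construction
(disjoint causal sets, linkage equilibrium), so eigenvalues sit close
to their permutation null and the test is conservative even though all
axes carry real biology.  The pipeline therefore uses
min(5, n<sub>traits</sub> − 1) axes by default — matching the emulated
analysis, which retained five of six — and reports the test result
alongside; pass `dim=` to override.

## Unique-accession consensus

For each of `reps` hypervolume pairs (accession-side, F2-side) built on
subsamples, an accession occurs in the pair's unique component if it is
(i) within the accession subsample's occupied region and (ii) outside
the F2 subsample's occupied region.  Occupancy is judged by nearest-
neighbour distance to the fitted subsample with a self-calibrated
radius: the 95th percentile of the subsample's own nearest-neighbour
spacings.  A query farther from every F2 point than F2 points typically
are from each other occupies space the F2s never reached.  Two
alternatives were rejected on measured grounds: proximity to the
Monte-Carlo unique-component subcloud inherits the cloud's sparseness
as noise (the subcloud hugs the F2 boundary, so interior accessions sit
within one characteristic spacing of it), and the one-class boundary
itself both excludes the extreme ~ν of the accession panel — exactly
the accessions being looked for — and extends a smooth RBF margin of
order 1.5 SD past the F2 extremes, swallowing genuine outliers.

Per run, accessions are ranked by occurrence count (ties broken by id)
and the shortest prefix covering 95% of all occurrences is kept,
extended inclusively over ties at the boundary.  The final consensus
keeps accessions present in at least `min_count` of the runs (desk
default 3 of 5; the emulated analysis used 6 of 10).  With five
accessions planted 6 SD beyond the F2 range among 180, the procedure
recovers 5/5 in every tested seed with 0–2 false positives in most;
occasional seeds flag a few extra margin accessions because each parent
has only ~3.6 F2 descendants at desk scale (about half the emulated
study's coverage), leaving their neighbourhoods thinly sampled.

## Q<sub>ST</sub>–F<sub>ST</sub>, transgression, SMA

Q<sub>ST</sub> uses method-of-moments variance components for
unbalanced one-way designs, clipped to [0, 1]; groups of size 1 are
dropped with a warning.  The 95% interval is a parametric bootstrap
(resimulate from fitted components under the same design, re-estimate;
the interval is widened to contain the point estimate if a bootstrap
quantile falls inside it).  The denominator is
V<sub>among</sub> + V<sub>within</sub> with no factor 2 — appropriate
for selfing lines.

Weir–Cockerham θ is the standard diploid multi-population estimator
(components a, b, c from sample sizes, allele frequencies and observed
heterozygote frequencies); fully inbred panels simply contribute
observed heterozygosity ≈ 0.  Monomorphic SNPs return NaN.  The
permutation null pools θ over all SNPs and label permutations (default
1,000); the threshold is the 95th percentile with linear interpolation,
and the neutral F<sub>ST</sub> is the median of θ strictly above it.

CVs for transgression use the n−1 denominator on the transformed
measurement scales — the scales every other analysis runs on.  CV is
scale-sensitive, so ratios are not comparable across different
transform choices.  SMA fits use the closed form
slope = sign(r)·SD<sub>y</sub>/SD<sub>x</sub> with the correlation
t-test (n−2 df) for significance.

## Diversity windows

π per site is c<sub>alt</sub>·c<sub>ref</sub> / C(n, 2) over
non-missing allele copies (two per diploid); window π divides the site
sum by the window length in bp.  Windows tile each chromosome from
position 1, non-overlapping and 1-based; trailing partial windows are
retained and flagged.  Tajima's D uses the standard constants computed
for the window's sample size, taken as the median of per-site
non-missing allele counts over segregating sites (missingness varies by
site; the median keeps the classical single-n formula).  Windows with
no segregating sites, or fewer than 4 allele copies, are undefined
(NaN).  D is invariant to ref/alt label swaps; π and D are fully
deterministic.

## Problem sizes and defaults

Defaults throughout are desk-scale: 180 accessions / 640 F2s / 1,000
SNPs for simulated conditions; 10 hypervolume replicates, 100
subsample pairs and 5 consensus runs for the outlier procedure
(the emulated analysis used 100 replicates, 10,000 pairs and 10 runs);
500 Monte-Carlo candidates per data point for volumes; 1,000
permutations for the F<sub>ST</sub> null; 500 bootstrap replicates for
Q<sub>ST</sub> intervals.  All stochastic procedures accept a single
seed and derive per-step seeds by counter, so identical seeds reproduce
results bit-for-bit.

## Known limitations

- Monte-Carlo volumes in d = 5 carry ~15% boundary bias at default
  sampling; comparisons between groups estimated with identical
  settings are much more accurate than absolute volumes.
- The Q<sub>ST</sub> interval is a parametric bootstrap, not an MCMC
  credible interval; coverage matches nominal only under the fitted
  normal components.
- The pooled permutation null for F<sub>ST</sub> ignores per-SNP
  sample-size differences; with heavy missingness a per-SNP null would
  be preferable.
- Consensus detection tolerances (the 95% occupancy radius quantile)
  were fixed against the synthetic conditions; panels with very uneven
  F2 sampling may need a different quantile.
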