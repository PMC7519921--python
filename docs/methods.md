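# Methods

## The synthetic cohort model

The generator emulates a small two-population exome cohort.  Background loci
follow the Balding–Nichols model: per locus an ancestral allele frequency
p ~ Uniform(0.05, 0.95), then independently for each population a
present-day frequency from Beta(p(1−F)/F, (1−p)(1−F)/F).  This Beta has mean
p and variance F·p(1−p), so the drift parameter F equals the expected
fixation index between the populations — which is what makes the model the
natural choice for testing F_st estimators by parameter recovery.  Genotypes
are Binomial(2, population frequency), i.e. Hardy–Weinberg within
populations and no linkage disequilibrium.

A configurable number of "planted" loci bypass the drift model and take an
explicit frequency pair (default 0.9/0.1).  The point of planting is known
truth for the selection stages, not realism: a selection-sweep model would
produce differentiated loci too, but without a clean truth table.

Defaults are the study conditions the package targets: 84 + 20 individuals
(the short-statured cohort and its sympatric control), 2000 loci, background
F = 0.03 — the weighted F_st actually observed between the two Cameroonian
populations — and 20 planted loci.  The phenotype is generated directly on
the height-SDS scale (the scale on which such cohorts are reported; no
growth-reference standard is assumed): height SDS = −(effect size) × (summed
planted dosage) + N(0, 1).  The default effect size is 0.1 SDS per allele;
with 20 planted loci at 0.9/0.1 the expected allele-load difference between
populations is ≈ 32 alleles, giving the ~3 SDS gap seen between the
populations of interest.  Genotype missingness is uniform at random
(default 2%), matching the absence of any reported missingness structure.

What the generator does **not** emulate: linkage disequilibrium, admixture or
migration, site-frequency-spectrum realism (the uniform ancestral prior
over-represents common variants), sequencing error, or batch effects in
depth/quality (QUAL and DP are written as constants in fixtures).  Passing
tests therefore demonstrate correctness of the statistics and the selection
machinery under the stated model, not robustness to LD-induced redundancy or
to structured missingness in real exomes.

The reporter-assay generator draws Renilla readings log-normally around
5×10^5 RLU and sets firefly = construct mean × Renilla × noise, with
log-normal noise of unit mean and coefficient of variation `cv`; the
normalized ratio is then unbiased for the construct mean and exactly equal
to it at cv = 0.

## F_st estimation

The primary estimator is Weir & Cockerham (1984), computed per biallelic
site from the three variance components a (among populations), b (among
individuals within populations) and c (within individuals), using sample
sizes, sample allele frequencies and observed heterozygote proportions.
The two reported aggregates follow the two standard conventions: mean F_st
is the average of per-site ratios a/(a+b+c); weighted F_st is the ratio of
sums Σa/Σ(a+b+c).  The mean-vs-weighted pairing is the reason this estimator
(rather than another F_st formulation) anchors the scan.

Numerical conventions, also flagged in output headers:

- Per-site estimates may be negative near F_st = 0; they are reported as
  computed and kept in aggregates.  Clamping at zero would bias the weighted
  aggregate upward.
- Sites with zero denominator (monomorphic in every population) are flagged
  undefined and excluded from aggregates; NaN never propagates.
- Nei's G_st = (H_T − H_S)/H_T is provided as a cross-check estimator; H_T
  uses the unweighted mean of population sample frequencies.  It needs only
  frequencies, so it also serves pairwise runs against external
  reference-panel frequency tables.

Tier selection: fixed thresholds select strictly greater-than; top-quantile
tiers (0.1% and 0.01% by default) realize their cutoff as the k-th largest
defined value (k = round(q·n), at least 1) and include boundary ties,
reporting the overflow.

## MAF correlation

Pearson r of the two frequency vectors over shared defined SNPs; reported as
r², with p from the t distribution at n − 2 degrees of freedom and a 95% CI
obtained by Fisher z-transforming r, back-transforming the bounds, squaring,
and ordering (with the lower bound set to 0 when the CI on r straddles zero).

## Sparse PLS

Sparsity is specified as a per-component count of retained variables
(keepX), matching how such selections are reported ("400 variables kept"),
rather than as a soft-threshold penalty.  With a univariate response the
cross-covariance direction w = Xᵀy is closed-form; the keepX largest-|w|
entries are retained, the rest zeroed, and the vector renormalized.  Scores
are t = Xw on the deflated matrix; deflation is regression-mode on both X
and y, which makes successive scores orthogonal (tested to 1e-8).  With
keepX = p the fit reduces to dense PLS (verified against an independent
NIPALS implementation).

Choices that were genuinely open:

- **Response.** Whether the original analysis regressed on population
  membership or on height SDS is not recorded; both are implemented
  (`binary_population` coding −1/+1, and `continuous_phenotype`), with the
  binary coding as default since the selection stage discriminates the two
  populations.
- **Component-2 keepX** defaults to 400, same as component 1, and is
  configurable.
- **Column scaling.** Dosage columns are centered and unit-variance scaled:
  dosage variance grows with MAF, and unscaled fits are dominated by common
  variants.
- **Determinism.** Loading signs are fixed by making the largest-|entry|
  coordinate positive; |w| ties at the keepX boundary break by variant index
  and are counted.  No randomization is used anywhere in the fit.

Missing dosages are mean-imputed per variant beforehand; fully-missing
variants are dropped with a logged count.

## Clustering shortlist

Selected variants are clustered over their allele-frequency profiles across
populations.  No linkage, metric or cut rule is canonical for this step, so
the defaults — complete linkage, Euclidean distance, cut by cluster count,
one representative per cluster chosen by maximum between-population
frequency contrast (max − min across profile columns, ties by row order) —
are all configurable and recorded in output metadata.  Gene annotation is
consumed from an external table and applied as a post-filter on
representatives; the package never computes gene assignments.

## Association statistics

Association is allelic: the 2×2 table of ref/alt allele counts by
population, one odds ratio per biallelic SNP.  (A genotypic dominant or
recessive carrier mode is exposed but not default.)  The CI is Wald on the
log odds ratio at 1.96; when any cell is zero, 0.5 is added to every cell
(Haldane–Anscombe) before both OR and CI.  The chi-square test is Pearson's
with df = 1, Yates correction off by default; a zero expected cell makes the
test undefined with a warning.  No multiple-testing correction is used for
selection — raw p-values are what such shortlists report — but Bonferroni
and Benjamini–Hochberg columns are emitted for transparency.

The candidate table subtracts an externally supplied reference-panel MAF
from the cohort MAF per variant and sorts by the difference, descending;
missing reference values yield an undefined difference, logged, never a
dropped row.  Published MAF values above 0.5 are taken as printed, not
re-folded.

## Reporter ANOVA

Each firefly/Renilla ratio is one observation; how technical and biological
replicates combine is left to the caller (the original report's triplicates
vs n = 6 is ambiguous, so no aggregation is imposed).  One-way ANOVA is
standard (F = MS_between/MS_within); the degenerate all-groups-zero-variance
case reports F = ∞, p = 0 with a warning rather than NaN.

## Pipeline

Stage order is fixed (ingest → filter → frequencies → F_st → tier → sPLS →
cluster → associate); all randomness flows from the single simulation seed,
artifacts are written with fixed float formatting and no timestamps, so a
run is byte-reproducible.  keepX is clamped to the tier size (with the
clamp recorded in the funnel report) since the tier can be smaller than 400.

## Problem sizes

Simulation-based tests use 50 + 50 samples with 2000–5000 loci and 10–20
seed replicates; calibration tests use 1000 null simulations.  These sizes
put Monte-Carlo error comfortably inside the asserted tolerances (e.g. the
weighted-F_st recovery tolerance of ±0.02 at F = 0.10 corresponds to ~5
standard errors of the 10-seed mean) while keeping the full suite under a
minute of compute.

## Known limitations

- The Weir–Cockerham scan assumes genotype data with observed
  heterozygosity; scans from frequency-only external panels fall back to
  G_st or Hardy–Weinberg-implied heterozygosity.
- No LD pruning or windowed statistics; every site is treated independently,
  as in the per-site scan it implements.
- The funnel's published intermediate cardinalities (tens of thousands of
  variants) are not reproducible from synthetic cohorts of desk scale; tests
  validate estimator correctness, recovery of planted truth, calibration,
  and determinism instead.
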