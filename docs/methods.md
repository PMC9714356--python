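# Methods

## The statistical model

For one CpG site and one SNP within a sample stratum (all samples, cases
only, or controls only), the association model is ordinary least squares on
the methylation beta scale:

    beta_cpg,i = b0 + b1 * g_i + b2 * age_i + e_i

with `g_i` the minor-allele dosage (0/1/2) of sample `i`. `b1` — the change
in methylation fraction per additional minor-allele copy — is reported with
its standard error, t statistic and two-sided p-value on n − 3 degrees of
freedom. Methylation is regressed untransformed (no M-value/logit step):
the effect sizes of interest are differences in methylation fraction, and
the bounded scale is handled in the simulation model rather than the
regression.

Multiple testing is controlled **per SNP**: for each SNP, the
Benjamini–Hochberg step-up runs across that SNP's family of testable CpGs,
and a pair is a discovery when q < alpha (strict; default alpha 0.05).
Degenerate pairs — fewer than 4 complete cases, constant dosage in the
stratum, dosage collinear with age, or a constant methylation response —
are counted as attempted, flagged, and excluded from the family size m. A
`global` FDR scope (one pooled family) is available but not the default,
because the scientific question is asked SNP by SNP. BH is used rather than
BY or q-value estimation: it is the standard default, and CpG-level
dependence within a family is positive-regression-dependent in the
situations this pipeline targets.

Missing data are handled by pairwise complete-case deletion per SNP–CpG
pair; age enters untransformed as a single linear covariate.

Two fitting routes exist deliberately: `fit_pair` (statsmodels OLS, one
pair at a time) and the vectorized scan (one normal-equations solve per
SNP for all fully observed CpGs). They are tested to agree to 1e-10; a
third, closed-form normal-equations oracle lives in the test suite only.

## Genotype calling

Each SNP probe's per-sample signal is clustered by 1-D k-means (Lloyd)
with centers initialized at 0.1, 0.5, 0.9, iterated to a center shift
below 1e-6 or 100 iterations. K-means with this fixed anchored
initialization is deterministic and reproducible; a Gaussian mixture would
add an EM dependence on starting values without changing well-separated
assignments. Empty clusters are legitimate (monomorphic or two-genotype
SNPs) and keep their center in place. A sample farther than
`max_cluster_distance` (default 0.2, half the inter-peak spacing) from
every center becomes a missing call.

Orientation counts the high-cluster allele as 2·n_high + n_het; whichever
allele is rarer becomes the minor allele and the per-sample code is its
copy number. An exact 50/50 tie keeps the high-cluster allele as minor —
any deterministic rule works, this one is documented. Orientation is
idempotent, and the folded MAF computed from oriented codes is ≤ 0.5 by
construction. Calling is joint across all samples (cases and controls
together); per-cohort calling would only differ for borderline clusters.

## Hardy–Weinberg exact test

QC uses the exact conditional test: conditioning on the observed allele
counts, the probability of every possible heterozygote count (same parity
as the minor-allele count) is computed from the multinomial/hypergeometric
kernel in log space, and the two-sided p-value sums the probabilities of
all outcomes no more probable than the observed one (ties included, with a
1e-12 relative tolerance for float rounding). The exact test is preferred
to the chi-square approximation because SNP panels of this kind are small
(62 SNPs) and the exact version admits a clean independent oracle —
exact-integer enumeration — against which the implementation is checked
exhaustively for every table with up to 50 individuals.

The three QC filters use strict inequalities exactly as stated (MAF
> 0.01, missing < 0.01, HWE p > 0.001), so boundary values fail. Missing
codes are excluded from both MAF and HWE counts (complete-case
convention). HWE can optionally be computed on one group only
(`hwe_group`), a common convention when cases might violate equilibrium at
trait-associated loci; the default is all samples.

## Cis/trans annotation

Same chromosome and distance strictly below the window (default 1 Mb) is
cis; same chromosome at or beyond the window is long-distance cis;
different chromosomes is trans. The boundary case (distance exactly 1 Mb)
is assigned to long-cis, a documented and configurable choice. Chromosome
labels are compared case-insensitively after stripping an optional `chr`
prefix, so mixed BED dialects interoperate; both annotation files must use
the same genome build — the package is build-agnostic. CpG position is the
probe's single annotated coordinate; SNP position is the variant
coordinate. BED input is 0-based half-open; internal positions are 1-based
(pos = start + 1).

## Differential calling

Cases and controls are scanned separately with identical settings. Every
pair significant in either stratum is labeled by the pattern of
significance (`case_only`, `control_only`, `both`); no formal
genotype-by-group interaction test is attempted — the design question is
where a regulatory relationship is detectable, not whether two
coefficients differ. Consequently stratum-unique labels partly reflect
power: a shared effect sitting near the per-stratum detection boundary can
fall on one side in cases and the other in controls. The calibration test
quantifies this (shared strong effects are miscategorized as unique in
≤ 10% of cases at n = 2000), and the acceptance script sizes its planted
demonstration effects (|delta| = 0.09 beta per allele) so that per-stratum
power is comfortable and labels reflect the planted strata.

Group differences in methylation at implicated CpGs use the Welch
(unequal-variance) two-sample t-test, two-sided; Welch is the safer
default when group variances differ. If both groups are constant the test
degenerates: p = 1 when the means agree, 0 otherwise. Pairs significant in
both strata with opposite effect signs carry an `opposite_direction` flag.

## The synthetic-data generator

The generator emulates the structure of a case/control 450K study:

* **Geometry defaults.** 689 samples with case fraction 354/689, 62 SNPs,
  ages uniform on [18, 70]. `n_cpgs` defaults to a desk-scale 5,000; the
  full 485,512 is supported for metadata-level work (the driver's dry run
  verifies the 30,101,744-pair enumeration without fitting anything).
* **Genotypes.** Per SNP, an allele frequency is drawn uniformly from
  `allele_freq_range` (default [0.05, 0.5]) and dosages are Binomial(2, f)
  per sample — Hardy–Weinberg by construction.
* **Probe signal.** dosage/2 plus Gaussian noise (default SD 0.03, a
  clearly separated three-peak signal; the tests also exercise SD 0.05),
  clipped to [0, 1], with an optional missing mask. The peak-centered
  Gaussian noise model is an assumption; nothing in the calling stage
  depends on it beyond peak separation.
* **Methylation.** Each CpG gets Beta shape parameters (a, b): either one
  pair for all CpGs, or (default) a hypo/hyper/intermediate mixture —
  40% Beta(2, 18), 40% Beta(18, 2), 20% Beta(8, 8) — mimicking the bimodal
  methylation landscape of arrays. The baseline level is a draw from that
  Beta; per-sample values are drawn from a Beta moment-matched to the
  linear predictor (baseline + planted dosage effects + age slope ×
  standardized age) with the CpG's precision a + b. Moment matching keeps
  values in [0, 1] without a clipping step dominating the distribution.
  Planted effects that would push the expected value outside [0, 1] for
  more than 1% of samples are rejected at generation time.
* **Group-restricted effects.** `case_only` / `control_only` effects
  multiply the dosage term by the group indicator; labels are
  Bernoulli(case_fraction) draws fixed per dataset.
* **Determinism.** A single `numpy` Generator seeded from the config;
  identical config + seed gives bit-identical outputs.

What the generator does **not** emulate: raw IDAT intensities, Infinium
I/II probe chemistry, batch effects, cell-type composition, genomic
correlation between neighboring CpGs, or linkage disequilibrium between
SNPs. Passing tests therefore demonstrate correctness of the statistical
machinery under a clean generative model, not robustness to those
real-data artifacts.

## Calibration and recovery checks: problem sizes and choices

The statistical test suite runs at sizes chosen to keep the whole suite
fast while leaving comfortable Monte-Carlo margins:

* **Null calibration**: 50 seeds of 20 SNPs × 500 CpGs at n = 300 with no
  planted effects; ≤ 10% of SNP families may show any BH discovery, and
  per-seed Kolmogorov–Smirnov uniformity of the 10,000 pair p-values must
  hold at the 0.01 level in ≥ 90% of seeds (testing KS per seed rather
  than on the pooled half-million p-values keeps the check sensitive to
  real miscalibration while tolerant of the O(1/n) deviations that
  finite-sample t approximations carry). These runs use the symmetric
  Beta(5, 5) baseline so that the calibration check isolates the
  regression machinery from the additional, well-understood small-sample
  skew effect of near-boundary CpGs.
* **Parameter recovery**: a planted −0.05 beta/allele effect at MAF 0.3,
  n = 2000, 50 seeds; the mean fitted effect must land within ±0.005 of
  truth, a case-only planted effect must be significant in the case
  stratum in every seed (per-stratum |t| ≈ 7), and its mean fitted effect
  in controls must be within 0.005 of zero.
* **Calling accuracy**: ≥ 99% concordance at probe-noise SD 0.05 with 200
  samples per peak; with peaks 0.5 apart, the misassignment probability
  per sample is about 2·Phi(−5) ≈ 6e-7, so the margin is dominated by the
  distance-based missing rule.

## Known limitations

* Stratum-unique calls conflate biology with power (see above); a formal
  interaction model would be needed to separate them.
* The scan materializes one result row per attempted pair; at full array
  scale (30.1M pairs per stratum) a chunked writer would be needed.
* Multi-allelic SNPs and sex-chromosome dosage are out of scope; the
  calling stage assumes at most three signal peaks.
* Cell-type heterogeneity and batch structure, major confounders in real
  methylation studies, are neither simulated nor adjusted for — the model
  carries exactly one covariate (age), by design.
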