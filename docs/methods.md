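# Methods

## Model and procedure

The pipeline targets variants whose disease relevance is mediated by
intermediate imaging traits. For a diagnostic contrast with subjects
pooled from one control and one case group, and imaging QTs
`y_1 … y_R` over R ROIs:

* **Step 1** fits, per ROI, the covariate-adjusted OLS model
  `y = β·x + Γ·Z + intercept + ε` with x the 0/1 diagnosis, and records
  `−log10(p)` of the two-sided exact-t test on β (df = n − k − 2 for k
  covariates). An intercept is always included: the model is about
  conditional mean differences and omitting it would confound covariate
  centering.
* **Step 2** fits the same model per ROI with the additive genotype
  (minor-allele count) in place of x, once per SNP, over the same pooled
  subject set. SNPs that are constant within the contrast subset carry no
  map and are excluded with a warning; subjects with a missing genotype are
  dropped pairwise per SNP, and `n_used` is recorded.
* **Step 3** computes the Pearson correlation between each SNP's map and the
  diagnostic map across ROIs, takes the analytic two-sided p (df = R − 2),
  Bonferroni-corrects over the family of SNP maps tested within the
  contrast, and declares significance at corrected p < 0.05. Maps are the
  *unsigned* `−log10(p)` vectors; per-ROI coefficient signs are recorded in
  the outputs but do not enter the correlation.

Numerically, all ROIs of one predictor share a design matrix, so each map is
a single multi-response least-squares solve; SNP scans with complete
genotypes reduce further, via Frisch–Waugh–Lovell residualisation, to one
matrix product over covariate-residualised genotypes and QTs. Both routes
are algebraically exact OLS, and the test suite pins them to a closed-form
normal-equations oracle at 1e−8. p-values are floored at 1e−300, so map
values top out at 300 (configurable).

## Quality control

Per-SNP filters with strict inequalities: call rate > 0.95, minor allele
frequency > 0.05 (computed on non-missing calls, no imputation), exact
conditional Hardy–Weinberg test p > 1e−6. The HWE test conditions on the
observed allele counts; the heterozygote count then has a
hypergeometric-type null, evaluated by an outward recurrence from the modal
configuration, and the p-value is the summed probability of all
configurations no more probable than the observed one (standard tail, no
mid-p). QC runs cohort-wide once, before contrast subsetting, matching
common practice; per-contrast QC is possible by filtering a subsetted
matrix.

## Baselines

Three direct SNP–diagnosis analyses share the Bonferroni family with Step 3
so comparisons are at matched α: (1) logistic regression of diagnosis on
genotype plus covariates (Newton/IRLS, tolerance 1e−8, ≤ 100 iterations)
with a Wald two-sided p on the genotype coefficient — complete separation is
flagged, not reported as a p-value; a linear-probability variant exists
behind a flag; (2) Pearson correlation of genotype with numeric 0/1
diagnosis; (3) partial correlation given covariates (correlation of the two
OLS residual vectors, df = n − 2 − k), which collapses exactly to (2) when
no covariates are supplied.

## Synthetic cohorts

The generator emulates the data layout the pipeline consumes with a known
causal structure; every effect size is in units of the per-ROI noise SD
(1.0) so power arithmetic is transparent.

* Genotypes: independent per SNP, two allele draws per subject at the
  stated MAF (hence Hardy–Weinberg proportions), optional missingness.
  No linkage disequilibrium between loci is modelled.
* Covariates: age ~ U(60, 90) years, sex ~ Bernoulli(0.5), education
  ~ U(12, 20) years — late-life memory-clinic magnitudes, zero effect on
  QTs by default.
* QTs: baseline 1.2 (an SUVR-like offset with no inferential effect) plus
  0.8 per minor allele on each causal ROI for each causal SNP, plus
  covariate effects, plus unit Gaussian noise.
* Diagnosis: liability threshold. The liability is the weighted sum of the
  subject's pre-disease-effect QTs (weights uniform over the causal ROIs)
  plus Gaussian noise, thresholded at the case-fraction sample quantile
  (default 0.45). There is deliberately **no direct SNP → diagnosis edge**;
  with the SNP effect set to zero the marginal SNP–diagnosis test is
  calibrated, which the suite checks. After assignment, cases receive an
  additional 0.5-SD shift on the affected ROIs (the disease's own imaging
  signature); multi-class stages are emulated by splitting cases into
  liability-ranked tiers with increasing shifts.
* Reference conditions: the "power" configuration uses 600 subjects, 116
  ROIs, 54 SNPs, 2 causal SNPs over 30 ROIs at 0.8 SD/allele, and liability
  noise SD 4. The last choice keeps the marginal genotype–diagnosis
  correlation near 0.1 — individually undetectable after Bonferroni at
  n = 600 — while each causal ROI regression carries t ≈ 4–5, which is the
  mediated-signal regime the method is designed for. The "null"
  configuration zeroes every effect and the liability weights, so all
  association tests are under their global null. The null-experiment
  fixture widens the SNP panel to 254 (a 54-SNP hypothesis panel containing
  6 causal loci plus a 200-SNP null pool), mirroring a candidate panel
  enriched with true signals.

What the generator does *not* emulate: LD structure, spatially correlated
ROI noise, covariate–diagnosis confounding, genotyping batch effects, or
voxel-level data. Passing tests therefore demonstrate the statistical
machinery under clean mediation, not robustness to those real-data
features.

## Simulation scales

The test-bench sizes are chosen to give stable Monte-Carlo assertions on a
single CPU: 1000 replicates for type-I calibration and family-wise error
(binomial 3-SD tolerance ≈ ±0.021 at the 5% level), 100 replicates for
detection-rate comparisons, 100,000 draws for the permutation-vs-analytic
p check, 300 random sets in the null experiment (the full-scale experiment
uses 10,000 behind a config value).

## Known limitations

* **The analytic Step-3 p is anti-conservative in the far tail.** Under the
  null, map entries are `−log10(uniform)` — strongly right-skewed — and the
  t/beta-based Pearson p assumes bivariate normality. At R = 116 the
  per-SNP tail probability at the Bonferroni threshold is roughly twice
  nominal, and the measured family-wise error of the analytic pipeline on
  all-null cohorts is ≈ 0.09–0.11 rather than ≤ 0.05. The ROI-permutation
  option (`correlate_maps(..., method="permutation")`) is exact under
  exchangeability and restores FWER ≤ 0.05 (measured ≈ 0.01–0.04); it costs
  one permutation null per SNP and is the right choice whenever calibrated
  error control matters more than matching the analytic convention.
* **Inter-map correlation inflates null SNPs in the presence of real
  structure.** All SNP maps within a contrast share the same QT noise, and
  a chance correlation between a null genotype and the causal-QT burden
  elevates that SNP's map on every causal ROI simultaneously. Random SNP
  sets therefore yield nonzero finding counts on cohorts with real
  diagnostic structure — which is exactly why the random-set null
  experiment, which calibrates the panel count against same-size random
  draws, is part of the pipeline rather than an afterthought.
* ROI maps from real imaging are spatially correlated; the analytic Step-3
  p treats ROIs as independent pairs. The permutation option addresses
  exchangeability of labels but not spatial smoothness within a map.
* Degenerate inputs: constant predictors, constant maps, rank-deficient
  designs, and separation in the logistic baseline raise (or flag) rather
  than return numbers; tie-breaking in the HWE tail uses a 1e−12 relative
  tolerance when comparing configuration probabilities.
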