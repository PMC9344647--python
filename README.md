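# endomap

Identify disease-associated genetic variants **enriched by brain-imaging
endophenotypes**: score each candidate SNP by how closely its brain-wide
pattern of effects on imaging quantitative traits (QTs) resembles the
disease's own pattern, instead of testing the SNP against the diagnosis
directly.

## Who this is for

Imaging-genetics studies of moderately sized cohorts (hundreds of subjects)
in which a binary case/control test is underpowered, but regional imaging
measures — e.g. amyloid-PET SUVR means over the 116 AAL atlas regions — sit
on the causal path between genotype and diagnosis. When a variant influences
disease *through* such intermediate brain traits, its signature is visible in
the imaging data long before it is visible in the case/control table.

## The method

For one diagnostic contrast (e.g. CN vs AD) with covariates Z (age, sex,
education), and for each ROI's quantitative trait y:

1. **Imaging–diagnosis map.** Fit `y = β·x + Γ·Z + ε` per ROI, where x is
   the 0/1 diagnosis. Stack `−log10(p)` of the β-test over ROIs: the
   diagnostic effect map.
2. **Imaging–genetics maps.** Fit `y = α·g + Γ·Z + ε` per ROI for each SNP's
   additive genotype g (0/1/2 minor alleles). One `−log10(p)` map per SNP —
   with 54 SNPs and 116 ROIs this is 6,264 regressions.
3. **Map correlation.** For each SNP, compute the Pearson correlation r
   between its genetic map and the diagnostic map across ROIs, with a
   two-sided p from `t = r·√((n−2)/(1−r²))`; Bonferroni-correct over the SNP
   family and call SNPs with corrected p < 0.05 significant.

The package also implements the standard genotype QC (call rate > 95%,
MAF > 5%, exact Hardy–Weinberg p > 1e−6), the three direct baselines it is
benchmarked against (covariate-adjusted logistic GWAS, Pearson and partial
correlation of SNP with diagnosis), a random-SNP-set null experiment, and a
synthetic-cohort generator with a planted SNP → QT → diagnosis mediation
structure so the full pipeline is testable without any restricted data.

## Worked example

`examples/04_map_correlation_vs_baselines.py` simulates a 600-subject cohort
in which two SNPs shift 30 ROIs by 0.8 noise-SDs per allele and influence
diagnosis only through those QTs, then runs Step 3 and the baselines:

```
map-correlation method (Bonferroni over 54 SNPs):
  *snp0000: r=+0.953  corrected p=1.83e-59  significant=True
   snp0039: r=+0.536  corrected p=3.07e-08  significant=True
   snp0035: r=+0.392  corrected p=7.31e-04  significant=True
  significant SNPs: 4

direct baselines, planted SNPs only (corrected p):
  snp0000 gwas     statistic=+0.198  corrected p=1.000  significant=False
  snp0000 pearson  statistic=+0.070  corrected p=1.000  significant=False
  snp0000 partial  statistic=+0.067  corrected p=1.000  significant=False
  snp0001 gwas     statistic=+0.323  corrected p=0.310  significant=False
```

The starred rows are the planted causal SNPs: the map correlation finds them
at astronomical significance (r ≈ 0.95 across 116 ROIs) while every direct
SNP–diagnosis test fails to reject at the same corrected α — the mediated
signal is spread too thinly over the binary outcome. The unstarred
significant rows are nulls promoted by inter-map correlation; see
`docs/methods.md` for why the analytic Step-3 p is optimistic and when to
prefer the permutation option.

The other examples cover cohort simulation and file output (`01`), QC
(`02`), effect maps (`03`) and the random-SNP-set null experiment (`05`).
A thin CLI mirrors the library: `endomap simulate | qc | step1 | step2 |
step3 | baselines | nullexp | all`.

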