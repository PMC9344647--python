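"""Random-SNP-set null experiment.

Draws many same-size random SNP sets from a null pool, runs the full
map-correlation pipeline on each, and places the hypothesis panel's count
of significant findings on the resulting null histogram.
"""

from endomap import compare_to_reference, run_null_experiment, simulate_cohort
from endomap.nullexp import _count_significant
from endomap.simulate import power_config

# 254 SNPs: a 54-SNP hypothesis panel (6 of them truly causal) plus a
# 200-SNP null pool for the random draws
cohort = simulate_cohort(power_config(seed=5, n_snps=254, n_causal_snps=6))
contrast = cohort.contrast("AD")
panel = cohort.genotypes.subset_snps(cohort.genotypes.snp_ids[:54])
pool = cohort.genotypes.subset_snps(cohort.genotypes.snp_ids[54:])

reference = _count_significant(cohort.qts, panel, contrast, alpha=0.05)
result = run_null_experiment(cohort.qts, pool, contrast,
                             set_size=54, n_sets=200, seed=6)
pct = compare_to_reference(result, reference)

print(f"hypothesis panel: {reference} significant SNPs")
print(f"random 54-SNP null sets ({result.n_sets}): "
      f"mean {result.counts.mean():.2f}, max {result.counts.max()}")
print(f"panel outperforms {100 * pct:.2f}% of random sets")
print("\nnull histogram (count: frequency):")
for _, row in result.histogram().iterrows():
    print(f"  {row['count']:3d}: {'#' * int(row['frequency'])}")
result.plot("scratch/null_histogram.png")
print("\nhistogram figure written to scratch/null_histogram.png")
# Random sets still yield a few findings each (inter-map correlation makes
# the analytic Step-3 p optimistic), but the enriched panel clearly
# outperforms the null distribution.
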