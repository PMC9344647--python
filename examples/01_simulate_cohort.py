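"""Generate a synthetic imaging-genetics cohort and write it to disk.

The cohort has a planted mediation structure: two causal SNPs shift 30
brain ROIs, and diagnosis is assigned by thresholding a liability score
built from those same ROIs — so the SNPs influence diagnosis only through
the imaging traits.
"""

from endomap import simulate_cohort, write_cohort
from endomap.simulate import power_config

cfg = power_config(seed=42)
cohort = simulate_cohort(cfg)

print("subjects:", cohort.qts.n_subjects)
print("ROIs:", cohort.qts.n_rois, "| SNPs:", cohort.genotypes.n_snps)
print("diagnosis counts:", cohort.diagnosis.value_counts().to_dict())
print("planted causal SNPs:", cohort.truth.causal_snp_ids)
print("per-allele QT shift (noise-SD units):", cohort.truth.snp_effect_size)

paths = write_cohort(cohort, "scratch/example_cohort")
print("\nwritten files:")
for kind, path in paths.items():
    print(f"  {kind}: {path}")
# The VCF + TSVs are everything the pipeline needs; truth.json records the
# planted signal so downstream results can be scored against ground truth.
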