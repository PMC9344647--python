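"""Genotype quality control: call rate, minor allele frequency, exact HWE.

Builds a small genotype matrix with three planted failures (one per
criterion) and shows the per-SNP QC report.
"""

import numpy as np

from endomap import GenotypeMatrix, apply_qc
from endomap.datatypes import MISSING

rng = np.random.default_rng(0)
n = 200

columns = {f"rs_good{j}": rng.binomial(2, 0.3, n) for j in range(3)}
low_call = rng.binomial(2, 0.3, n)
low_call[:20] = MISSING                       # call rate 0.90 (fails > 0.95)
columns["rs_lowcall"] = low_call
rare = np.zeros(n, dtype=int)
rare[:8] = 1                                  # MAF 0.02 (fails > 0.05)
columns["rs_rare"] = rare
columns["rs_allhet"] = np.ones(n, dtype=int)  # all heterozygous: HWE p ~ 1e-60

gm = GenotypeMatrix(
    np.column_stack(list(columns.values())),
    [f"S{i}" for i in range(n)],
    list(columns),
)
filtered, report = apply_qc(gm)
print(report.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\n{filtered.n_snps} of {gm.n_snps} SNPs pass QC")
# Each row shows the computed metric next to the strict thresholds
# (call rate > 95%, MAF > 5%, exact HWE p > 1e-6).
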