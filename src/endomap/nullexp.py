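"""Random-SNP-set null experiment.

Repeatedly draw same-size SNP sets from a pool of "uninteresting" loci, run
the full map-correlation pipeline on each draw, and record the number of
significant findings.  The count from a designated hypothesis set (e.g. a
panel of known susceptibility loci) is then placed on that null histogram:
``percentile_outperformed`` is the fraction of random sets that yielded
strictly fewer findings than the hypothesis set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import Contrast, EffectMap, GenotypeMatrix, QTMatrix
from .association import diagnosis_effect_map, snp_effect_maps
from .mapcorr import DEFAULT_ALPHA, correlate_maps

log = logging.getLogger(__name__)

DEFAULT_N_SETS = 1_000  # 10,000 reproduces the full-scale experiment


@dataclass
class NullExperimentResult:
    """Distribution of significant-SNP counts over resampled null sets."""

    counts: np.ndarray
    n_sets: int
    set_size: int
    seed: int
    reference_count: int | None = None
    percentile_outperformed: float | None = None

    def histogram(self) -> pd.DataFrame:
        """Count-frequency table of the null distribution."""
        vals, freq = np.unique(self.counts, return_counts=True)
        return pd.DataFrame({"count": vals, "frequency": freq})

    def plot(self, path) -> None:
        """Histogram of null counts with the reference count marked."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        upper = int(max(self.counts.max(initial=0), self.reference_count or 0)) + 2
        ax.hist(self.counts, bins=np.arange(-0.5, upper + 0.5), color="steelblue")
        if self.reference_count is not None:
            ax.axvline(self.reference_count, color="red", linestyle="--",
                       label=f"hypothesis set: {self.reference_count}")
            ax.legend()
        ax.set_xlabel("significant SNPs per random set")
        ax.set_ylabel("number of sets")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _count_significant(
    qts: QTMatrix, genotypes: GenotypeMatrix, contrast: Contrast,
    alpha: float, dx_map: EffectMap | None = None,
) -> int:
    dx = dx_map if dx_map is not None else diagnosis_effect_map(qts, contrast)
    result = snp_effect_maps(qts, genotypes, contrast)
    assocs = correlate_maps(dx, result.maps, alpha=alpha)
    return sum(a.significant for a in assocs)


def run_null_experiment(
    qts: QTMatrix,
    genotype_pool: GenotypeMatrix,
    contrast: Contrast,
    set_size: int,
    n_sets: int = DEFAULT_N_SETS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> NullExperimentResult:
    """Apply the pipeline to ``n_sets`` random ``set_size``-SNP draws
    (without replacement within a draw, independent across draws) from
    ``genotype_pool`` and record each draw's significant-SNP count.

    The diagnostic map does not depend on the drawn SNPs and is computed
    once.  Deterministic given ``seed``.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    if genotype_pool.n_snps < set_size:
        raise ValidationError(
            f"pool has {genotype_pool.n_snps} SNPs, fewer than set_size={set_size}"
        )
    rng = np.random.default_rng(seed)
    dx_map = diagnosis_effect_map(qts, contrast)
    counts = np.zeros(n_sets, dtype=int)
    for i in range(n_sets):
        pick = rng.choice(genotype_pool.n_snps, size=set_size, replace=False)
        subset = GenotypeMatrix(
            genotype_pool.values[:, pick],
            genotype_pool.subject_ids,
            genotype_pool.snp_ids[pick],
        )
        counts[i] = _count_significant(qts, subset, contrast, alpha, dx_map)
    log.info("null experiment: %d sets of %d SNPs, mean count %.3f",
             n_sets, set_size, counts.mean())
    return NullExperimentResult(counts=counts, n_sets=n_sets, set_size=set_size, seed=seed)


def compare_to_reference(result: NullExperimentResult, reference_count: int) -> float:
    """Fraction of resampled null counts strictly below the hypothesis
    set's count (ties do not count as outperformed)."""
    if result.counts.size == 0:
        raise ValidationError("null experiment has no counts")
    pct = float((result.counts < reference_count).mean())
    result.reference_count = int(reference_count)
    result.percentile_outperformed = pct
    return pct
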