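"""Genotype quality control.

Per-SNP filters with the standard thresholds used in candidate-SNP studies:
genotyping call rate > 95%, minor allele frequency > 5%, and exact
Hardy-Weinberg equilibrium test p > 1e-6.  All inequalities are strict.

The HWE test is the exact conditional test (the PLINK default): conditioning
on the observed allele counts, the number of heterozygotes follows a
hypergeometric-type null distribution, and the p-value is the total
probability of all heterozygote counts whose configuration is no more
probable than the observed one (standard tail definition, no mid-p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_CALL_RATE_MIN = 0.95
DEFAULT_MAF_MIN = 0.05
DEFAULT_HWE_P_MIN = 1e-6


@dataclass(frozen=True)
class QCThresholds:
    """Strict lower bounds a SNP must exceed to pass QC."""

    call_rate_min: float = DEFAULT_CALL_RATE_MIN
    maf_min: float = DEFAULT_MAF_MIN
    hwe_p_min: float = DEFAULT_HWE_P_MIN


@dataclass
class QCReport:
    """Per-SNP QC metrics and pass/fail flags, plus the thresholds used."""

    table: pd.DataFrame  # columns: snp_id, call_rate, maf, hwe_p, pass
    thresholds: QCThresholds

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def call_rate(genotype_column: np.ndarray) -> float:
    """Fraction of subjects with a non-missing call at this SNP."""
    g = np.asarray(genotype_column)
    if g.size == 0:
        raise ValidationError("empty genotype column")
    return float((g != MISSING).sum() / g.size)


def minor_allele_frequency(genotype_column: np.ndarray) -> float:
    """min(f, 1-f) for the allele frequency f among non-missing calls."""
    g = np.asarray(genotype_column)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise ValidationError("cannot compute MAF: all genotypes missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


@lru_cache(maxsize=100_000)
def _het_probabilities(n: int, n_minor: int) -> np.ndarray:
    """Null probabilities of each attainable heterozygote count.

    Conditional on ``n`` diploid individuals carrying ``n_minor`` copies of
    the minor allele, returns P(n_het = h) for h = parity, parity+2, ...,
    n_minor (h shares the parity of n_minor and cannot exceed either allele
    count).  Computed by an outward recurrence from the most probable value
    to avoid overflow, then normalised.

    The adjacent-count ratio follows from the conditional likelihood
    P(h) ∝ 1 / (h! * n_hom_minor! * n_hom_major!) * 2^h:

        P(h+2) / P(h) = 4 * n_hom_minor(h) * n_hom_major(h) / ((h+2)(h+1))
    """
    n_major = 2 * n - n_minor
    if n_minor > n_major:
        raise ValueError("n_minor must be the rarer allele count")
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    if len(hets) == 0:  # n_minor == 0 handled by caller, but be safe
        return np.ones(1)
    # start at the mode: expected het count under HWE, snapped to parity
    mid = int(round(n_minor * n_major / (2.0 * n)))
    if mid % 2 != n_minor % 2:
        mid += 1 if mid + 1 <= n_minor else -1
    mid = min(max(mid, hets[0]), hets[-1])
    probs = np.zeros(len(hets))
    i_mid = int((mid - hets[0]) // 2)
    probs[i_mid] = 1.0
    # downwards: P(h-2) = P(h) * h*(h-1) / (4 * (n_hom_min+1) * (n_hom_maj+1))
    for i in range(i_mid, 0, -1):
        h = hets[i]
        hom_min = (n_minor - h) // 2
        hom_maj = (n_major - h) // 2
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_min + 1) * (hom_maj + 1))
    # upwards: P(h+2) = P(h) * 4*hom_min*hom_maj / ((h+2)*(h+1))
    for i in range(i_mid, len(hets) - 1):
        h = hets[i]
        hom_min = (n_minor - h) // 2
        hom_maj = (n_major - h) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_min * hom_maj / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    return probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test p-value.

    Arguments are the three genotype counts (either homozygote may be given
    first).  Returns the summed null probability of all heterozygote counts
    whose configuration probability does not exceed the observed one.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValidationError(f"genotype counts must be non-negative integers, got {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValidationError("cannot test HWE on zero genotypes")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0  # monomorphic: single attainable configuration
    probs = _het_probabilities(n, n_minor)
    i_obs = (n_het - n_minor % 2) // 2
    # tolerate float round-off when comparing "no more probable than observed"
    p = probs[probs <= probs[i_obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def snp_qc_metrics(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, MAF and exact HWE p (NaN where undefined)."""
    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        g = genotypes.values[:, j]
        cr = call_rate(g)
        obs = g[g != MISSING]
        if obs.size == 0:
            rows.append((snp, cr, np.nan, np.nan))
            continue
        maf = minor_allele_frequency(g)
        n_ref = int((obs == 0).sum())
        n_het = int((obs == 1).sum())
        n_alt = int((obs == 2).sum())
        rows.append((snp, cr, maf, hwe_exact_test(n_ref, n_het, n_alt)))
    return pd.DataFrame(rows, columns=["snp_id", "call_rate", "maf", "hwe_p"])


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNP columns failing any criterion; subjects are never dropped.

    A SNP passes iff call_rate > call_rate_min AND maf > maf_min AND
    hwe_p > hwe_p_min (strict inequalities).  SNPs with no data at all fail.
    """
    thresholds = thresholds or QCThresholds()
    table = snp_qc_metrics(genotypes)
    with np.errstate(invalid="ignore"):
        passed = (
            (table["call_rate"] > thresholds.call_rate_min)
            & (table["maf"] > thresholds.maf_min)
            & (table["hwe_p"] > thresholds.hwe_p_min)
        )
    table["pass"] = passed.fillna(False)
    report = QCReport(table=table, thresholds=thresholds)
    keep = table.loc[table["pass"], "snp_id"].tolist()
    if not keep:
        warnings.warn("no SNPs passed QC; returning an empty genotype matrix")
    log.info(
        "QC: %d of %d SNPs pass (call rate > %g, MAF > %g, HWE p > %g)",
        len(keep), genotypes.n_snps, thresholds.call_rate_min,
        thresholds.maf_min, thresholds.hwe_p_min,
    )
    filtered = GenotypeMatrix(
        genotypes.values[:, table["pass"].to_numpy(bool)],
        genotypes.subject_ids,
        np.asarray(keep, dtype=object),
    )
    return filtered, report
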