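"""Step 3: score each SNP by the Pearson correlation between its genetic
effect map and the diagnostic effect map across ROIs.

The two maps are the unsigned -log10(p) vectors from Steps 1-2, compared
ROI-by-ROI in a fixed common order.  Significance of the correlation uses
the analytic two-sided t-based p (df = n_rois - 2) by default; a
ROI-label permutation p is available because ROI maps are spatially
correlated and the analytic p assumes independent pairs.  Raw p-values are
Bonferroni-corrected over the family of SNP maps tested within one
diagnostic contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AlignmentError, DegenerateDesignError, ValidationError
from .datatypes import EffectMap, MapAssociation

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def pearson_r(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided analytic p-value.

    Equivalent to the exact-t test with t = r*sqrt((n-2)/(1-r^2)) on
    n - 2 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError("vectors must be 1-D and of equal length")
    if len(a) < 3:
        raise ValidationError("need at least 3 pairs to correlate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDesignError("cannot correlate a constant vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(max(res.pvalue, 1e-300))


def permutation_p(
    a: np.ndarray, b: np.ndarray, n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p for the Pearson correlation of ``a`` and
    ``b`` under random relabelling of the ROI axis of ``b``.

    Uses the add-one estimator (1 + #{|r_perm| >= |r_obs|}) / (1 + B).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r_obs, _ = pearson_r(a, b)
    rng = np.random.default_rng(seed)
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    n = len(a)
    hits = 0
    chunk = max(1, min(n_permutations, 20_000_000 // max(n, 1)))
    done = 0
    thresh = abs(r_obs) * (1 - 1e-12)
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        r_perm = bz[perms] @ az / n
        hits += int((np.abs(r_perm) >= thresh).sum())
        done += m
    return (1 + hits) / (1 + n_permutations)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p: min(1, m * p_raw)."""
    if m < 1:
        raise ValidationError(f"family size m must be >= 1, got {m}")
    if not 0.0 < p_raw <= 1.0:
        raise ValidationError(f"p-value must be in (0, 1], got {p_raw}")
    return float(min(1.0, m * p_raw))


def correlate_maps(
    dx_map: EffectMap,
    snp_maps: list[EffectMap],
    alpha: float = DEFAULT_ALPHA,
    family_size: int | None = None,
    method: str = "analytic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> list[MapAssociation]:
    """Correlate every SNP map with the diagnostic map and declare
    significance at Bonferroni-corrected ``alpha``.

    ``family_size`` defaults to the number of valid (non-degenerate) SNP
    maps; degenerate maps (constant across ROIs) are excluded with a
    warning and do not count toward the family.  Results are sorted by
    corrected p.  ROI order must match exactly; mismatches raise rather
    than silently reindexing.
    """
    if method not in ("analytic", "permutation"):
        raise ValidationError(f"unknown p-value method {method!r}")
    for m_ in snp_maps:
        if len(m_.roi_ids) != len(dx_map.roi_ids) or (m_.roi_ids != dx_map.roi_ids).any():
            raise AlignmentError(
                f"SNP map {m_.predictor_id!r} ROI order does not match the diagnostic map"
            )
    if np.ptp(dx_map.values) == 0:
        raise DegenerateDesignError("diagnostic map is constant across ROIs")

    valid: list[EffectMap] = []
    degenerate: list[str] = []
    for m_ in snp_maps:
        if np.ptp(m_.values) == 0:
            degenerate.append(m_.predictor_id)
        else:
            valid.append(m_)
    if degenerate:
        log.warning("excluding %d constant SNP map(s): %s", len(degenerate), degenerate[:10])
    m = family_size if family_size is not None else len(valid)

    out: list[MapAssociation] = []
    for snp_map in valid:
        r, p_analytic = pearson_r(dx_map.values, snp_map.values)
        if method == "permutation":
            p_raw = permutation_p(dx_map.values, snp_map.values, n_permutations, seed)
        else:
            p_raw = p_analytic
        p_corr = bonferroni(p_raw, m) if m >= 1 else 1.0
        out.append(
            MapAssociation(
                snp_id=snp_map.predictor_id,
                contrast=dx_map.predictor_id,
                r=r,
                p_raw=p_raw,
                p_corrected=p_corr,
                n_rois_used=len(dx_map.roi_ids),
                significant=bool(p_corr < alpha),
            )
        )
    out.sort(key=lambda a: (a.p_corrected, a.p_raw, a.snp_id))
    return out


def associations_frame(assocs: list[MapAssociation]) -> pd.DataFrame:
    """Tabulate Step-3 results (one row per SNP, sorted by corrected p)."""
    return pd.DataFrame(
        {
            "snp_id": [a.snp_id for a in assocs],
            "contrast": [a.contrast for a in assocs],
            "r": [a.r for a in assocs],
            "p_raw": [a.p_raw for a in assocs],
            "p_corrected": [a.p_corrected for a in assocs],
            "significant": [a.significant for a in assocs],
        }
    )
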