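"""Direct SNP-diagnosis association baselines.

Three comparator analyses against which the map-correlation method is
benchmarked:

* ``gwas_logistic`` — covariate-adjusted logistic regression of case/control
  status on the additive genotype (the standard GWAS model for a binary
  outcome), Wald two-sided p on the genotype coefficient.  A linear-probability
  variant is available behind a flag for sensitivity analysis.
* ``pearson_snp_dx`` — Pearson correlation of genotype with the numeric 0/1
  diagnosis.
* ``partial_corr_snp_dx`` — partial correlation of genotype with diagnosis
  given covariates (correlation of the two covariate-residualised vectors,
  t test with df = n - 2 - k).

All three are Bonferroni-corrected over the per-contrast SNP family, matching
the map-correlation method so the comparison is fair.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import DegenerateDesignError, ValidationError
from .datatypes import MISSING, Contrast, DirectAssociation, GenotypeMatrix
from .mapcorr import bonferroni

log = logging.getLogger(__name__)

_IRLS_TOL = 1e-8
_IRLS_MAXITER = 100


def _clean_xy(diagnosis: np.ndarray, g: np.ndarray, Z: np.ndarray | None):
    diagnosis = np.asarray(diagnosis, dtype=float)
    g = np.asarray(g, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    if diagnosis.shape != g.shape:
        raise ValidationError("diagnosis and genotype lengths differ")
    keep = np.isfinite(diagnosis) & np.isfinite(g)
    Zk = None
    if Z is not None and np.size(Z):
        Zarr = np.atleast_2d(np.asarray(Z, dtype=float))
        if Zarr.shape[0] != len(g):
            Zarr = Zarr.T
        keep &= np.isfinite(Zarr).all(axis=1)
        Zk = Zarr[keep]
    d, gk = diagnosis[keep], g[keep]
    if np.ptp(gk) == 0:
        raise DegenerateDesignError("genotype is constant on the analysed subjects")
    if np.ptp(d) == 0:
        raise DegenerateDesignError("only one diagnostic class present")
    return d, gk, Zk


def gwas_logistic(
    diagnosis: np.ndarray,
    g: np.ndarray,
    Z: np.ndarray | None = None,
    snp_id: str = "",
    contrast: str = "",
    family_size: int = 1,
    alpha: float = 0.05,
    model: str = "logistic",
) -> DirectAssociation:
    """Covariate-adjusted GWAS regression of diagnosis on additive genotype.

    Default is logistic regression fit by Newton/IRLS (tolerance 1e-8, at
    most 100 iterations) with a Wald two-sided p on the genotype
    coefficient.  Complete separation is flagged: the result carries
    ``converged=False`` and a missing (NaN) p rather than a spurious one.
    ``model="linear"`` substitutes the linear-probability model.
    """
    if model not in ("logistic", "linear"):
        raise ValidationError(f"unknown GWAS model {model!r}")
    d, gk, Zk = _clean_xy(diagnosis, g, Z)
    X = np.column_stack([np.ones(len(gk)), gk] + ([Zk] if Zk is not None else []))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("GWAS design matrix is rank deficient")

    if model == "linear":
        beta, se, t, p = _linear_wald(d, X)
        p_corr = bonferroni(p, family_size)
        return DirectAssociation(snp_id, contrast, "gwas", float(beta), float(p),
                                 p_corr, bool(p_corr < alpha))

    converged = True
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(d, X).fit(disp=0, maxiter=_IRLS_MAXITER, tol=_IRLS_TOL,
                                     method="newton")
            converged = bool(fit.mle_retvals.get("converged", False))
            beta = float(fit.params[1])
            se = float(fit.bse[1])
        except Exception as exc:  # statsmodels raises several types on separation
            converged = False
            beta, se = np.nan, np.nan
            note = f"fit failed: {type(exc).__name__}"
    if converged and (not np.isfinite(se) or se > 1e6 or abs(beta) > 50):
        converged = False
        note = note or "infinite-coefficient warning: probable complete separation"
    if not converged:
        note = note or "did not converge (possible complete separation)"
        log.warning("GWAS logistic fit for %s (%s): %s", snp_id or "<snp>", contrast, note)
        return DirectAssociation(snp_id, contrast, "gwas", beta, np.nan, np.nan,
                                 False, converged=False, note=note)
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))
    p_corr = bonferroni(p, family_size)
    return DirectAssociation(snp_id, contrast, "gwas", beta, p, p_corr,
                             bool(p_corr < alpha))


def _linear_wald(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float, float]:
    n, k = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - k)
    v = np.linalg.inv(X.T @ X)[1, 1]
    se = np.sqrt(sigma2 * v)
    t = coef[1] / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), n - k), 1e-300, 1.0))
    return coef[1], se, t, p


def pearson_snp_dx(
    diagnosis: np.ndarray,
    g: np.ndarray,
    snp_id: str = "",
    contrast: str = "",
    family_size: int = 1,
    alpha: float = 0.05,
) -> DirectAssociation:
    """Pearson correlation of additive genotype with numeric 0/1 diagnosis."""
    d, gk, _ = _clean_xy(diagnosis, g, None)
    res = stats.pearsonr(d, gk)
    p = float(np.clip(res.pvalue, 1e-300, 1.0))
    p_corr = bonferroni(p, family_size)
    return DirectAssociation(snp_id, contrast, "pearson", float(res.statistic),
                             p, p_corr, bool(p_corr < alpha))


def partial_corr_snp_dx(
    diagnosis: np.ndarray,
    g: np.ndarray,
    Z: np.ndarray | None = None,
    snp_id: str = "",
    contrast: str = "",
    family_size: int = 1,
    alpha: float = 0.05,
) -> DirectAssociation:
    """Partial correlation of genotype with diagnosis given covariates.

    Residualises both variables on [1, Z] by OLS, correlates the residuals,
    and tests with df = n - 2 - k.  With no covariates this reduces exactly
    to the plain Pearson baseline.
    """
    d, gk, Zk = _clean_xy(diagnosis, g, Z)
    n = len(d)
    k = 0 if Zk is None else Zk.shape[1]
    if k == 0:
        base = pearson_snp_dx(d, gk, snp_id, contrast, family_size, alpha)
        return DirectAssociation(snp_id, contrast, "partial", base.statistic,
                                 base.p_raw, base.p_corrected, base.significant)
    C = np.column_stack([np.ones(n), Zk])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(C, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(C)
        bad = sorted(int(i) - 1 for i in piv[rank:])
        raise DegenerateDesignError(f"covariate matrix rank deficient; columns {bad}")
    Q, _ = np.linalg.qr(C)
    rd = d - Q @ (Q.T @ d)
    rg = gk - Q @ (Q.T @ gk)
    if np.allclose(rd, 0, atol=1e-10 * max(1.0, np.abs(d).max())) or np.ptp(rd) == 0:
        raise DegenerateDesignError("diagnosis is an exact linear function of covariates")
    if np.allclose(rg, 0, atol=1e-10 * max(1.0, np.abs(gk).max())) or np.ptp(rg) == 0:
        raise DegenerateDesignError("genotype is an exact linear function of covariates")
    r = float(np.corrcoef(rd, rg)[0, 1])
    df = n - 2 - k
    if df <= 0:
        raise ValidationError("too few subjects for partial correlation")
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df), 1e-300, 1.0))
    p_corr = bonferroni(p, family_size)
    return DirectAssociation(snp_id, contrast, "partial", r, p, p_corr,
                             bool(p_corr < alpha))


def run_baselines(
    genotypes: GenotypeMatrix,
    contrast: Contrast,
    alpha: float = 0.05,
    family_size: int | None = None,
    gwas_model: str = "logistic",
) -> pd.DataFrame:
    """All three baselines for every SNP within one contrast.

    Returns a long-format table (snp_id, contrast, method, statistic, p_raw,
    p_corrected, significant, converged) — the combined comparison table.
    """
    G = genotypes.subset_subjects(contrast.subject_ids)
    m = family_size if family_size is not None else G.n_snps
    rows: list[DirectAssociation] = []
    for j, snp in enumerate(G.snp_ids):
        g = G.values[:, j]
        for fn, kwargs in (
            (gwas_logistic, {"Z": contrast.Z, "model": gwas_model}),
            (pearson_snp_dx, {}),
            (partial_corr_snp_dx, {"Z": contrast.Z}),
        ):
            try:
                rows.append(fn(contrast.x, g, snp_id=str(snp), contrast=contrast.name,
                               family_size=m, alpha=alpha, **kwargs))
            except DegenerateDesignError as exc:
                log.warning("baseline %s for %s skipped: %s", fn.__name__, snp, exc)
    return pd.DataFrame(
        {
            "snp_id": [a.snp_id for a in rows],
            "contrast": [a.contrast for a in rows],
            "method": [a.method for a in rows],
            "statistic": [a.statistic for a in rows],
            "p_raw": [a.p_raw for a in rows],
            "p_corrected": [a.p_corrected for a in rows],
            "significant": [a.significant for a in rows],
            "converged": [a.converged for a in rows],
        }
    )
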