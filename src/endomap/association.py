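"""Covariate-adjusted linear association of imaging QTs with diagnosis
(Step 1) and with each SNP (Step 2).

Both steps fit ordinary least squares with an intercept,

    y = b * predictor + Gamma * Z + intercept + error,

and test the predictor coefficient with a two-sided exact-t test
(df = n_used - k - 2 for k covariates).  A predictor's brain-wide
significance map stacks -log10(p) over ROIs in a fixed ROI order.

Implementation notes: all ROIs for one predictor share a design matrix, so
each map is a single multi-response least-squares solve.  For per-SNP maps
with complete genotype data this reduces further, via Frisch-Waugh-Lovell,
to one matrix product over covariate-residualised genotypes and QTs; both
routes are algebraically exact OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AlignmentError, DegenerateDesignError, ValidationError
from .datatypes import (
    MISSING,
    Contrast,
    EffectMap,
    EffectResult,
    GenotypeMatrix,
    QTMatrix,
)

log = logging.getLogger(__name__)

#: p-values below this floor are clamped before -log10 (so maps top out at 300)
P_FLOOR = 1e-300


def neglog10(p: float, floor: float = P_FLOOR) -> float:
    """-log10(p) with underflow clamping at ``floor``."""
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p-value must be in (0, 1], got {p}")
    return float(-np.log10(max(p, floor)))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise DegenerateDesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def _design(predictor: np.ndarray, Z: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    n = len(predictor)
    cols = [np.ones(n), predictor]
    names = ["intercept", "predictor"]
    if Z is not None and Z.size:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        if Z.shape[0] != n:
            raise AlignmentError("covariate rows do not match predictor length")
        cols.extend(Z[:, j] for j in range(Z.shape[1]))
        names.extend(f"covariate_{j}" for j in range(Z.shape[1]))
    return np.column_stack(cols), names


def _ols_multi(
    Y: np.ndarray, predictor: np.ndarray, Z: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """OLS of each column of ``Y`` on [1, predictor, Z].

    Returns (beta, se, t, p, df, gamma) where the first four are arrays over
    Y's columns for the predictor coefficient and gamma is the full
    coefficient matrix (params x responses).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(predictor):
        Y = Y.T
    predictor = np.asarray(predictor, dtype=float)
    if np.ptp(predictor) == 0:
        raise DegenerateDesignError("predictor is constant on the analysed subjects")
    X, names = _design(predictor, Z)
    n, k_total = X.shape
    df = n - k_total
    if df <= 0:
        raise ValidationError(f"too few subjects ({n}) for {k_total} design columns")
    _check_full_rank(X, names)
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ Y)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    # round-off guard: an (almost) exact fit is treated as residual-free
    yy = np.einsum("ij,ij->j", Y, Y)
    rss = np.where(rss < 1e-24 * np.maximum(yy, 1e-300), 0.0, rss)
    sigma2 = rss / df
    v11 = np.linalg.inv(XtX)[1, 1]
    beta = coef[1]
    se = np.sqrt(sigma2 * v11)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    return beta, se, t, p, df, coef


def fit_linear_effect(
    y: np.ndarray, predictor: np.ndarray, Z: np.ndarray | None = None
) -> EffectResult:
    """Covariate-adjusted OLS association of one QT with one predictor.

    Subjects with a missing (NaN or genotype no-call) predictor or QT value
    are dropped pairwise; ``n_used`` records the subjects actually fit.
    """
    y = np.asarray(y, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if y.shape != predictor.shape:
        raise AlignmentError("y and predictor lengths differ")
    predictor = np.where(predictor == MISSING, np.nan, predictor)
    keep = np.isfinite(y) & np.isfinite(predictor)
    if Z is not None and np.size(Z):
        Zarr = np.atleast_2d(np.asarray(Z, dtype=float))
        if Zarr.shape[0] != len(y):
            Zarr = Zarr.T
        keep &= np.isfinite(Zarr).all(axis=1)
        Zk = Zarr[keep]
    else:
        Zk = None
    beta, se, t, p, df, coef = _ols_multi(y[keep][:, None], predictor[keep], Zk)
    return EffectResult(
        beta=float(beta[0]),
        se=float(se[0]),
        t=float(t[0]),
        p=float(p[0]),
        n_used=int(keep.sum()),
        gamma=coef[2:, 0].copy(),
    )


def _aligned_arrays(qts: QTMatrix, contrast: Contrast) -> tuple[np.ndarray, np.ndarray]:
    """QT rows and covariate rows for the contrast's subjects, ID-joined."""
    sub = qts.subset_subjects(contrast.subject_ids)
    return sub.values, contrast.Z


def diagnosis_effect_map(qts: QTMatrix, contrast: Contrast, p_floor: float = P_FLOOR) -> EffectMap:
    """Step 1: regress every ROI's QT on diagnosis (plus covariates) and
    record -log10(p) of the diagnosis coefficient per ROI."""
    Y, Z = _aligned_arrays(qts, contrast)
    beta, _, _, p, _, _ = _ols_multi(Y, contrast.x, Z)
    values = -np.log10(np.clip(p, p_floor, 1.0))
    return EffectMap(
        predictor_id=contrast.name,
        roi_ids=qts.roi_ids,
        values=values,
        signs=np.sign(beta).astype(int),
    )


def top_rois(effect_map: EffectMap, k: int = 10) -> pd.DataFrame:
    """Ranked table of the k most significant ROIs in a map."""
    order = np.argsort(-effect_map.values, kind="stable")[:k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "roi_id": effect_map.roi_ids[order],
            "neglog10_p": effect_map.values[order],
        }
    )


@dataclass
class SnpEffectMaps:
    """Step-2 output: one significance map per analysable SNP.

    ``n_fits`` counts every ROI-level regression performed
    (#SNPs x #ROIs when nothing is excluded).  ``excluded`` lists SNPs that
    were constant within the contrast's subjects and could not be fit.
    """

    maps: list[EffectMap]
    contrast: str
    n_fits: int
    excluded: list[str] = field(default_factory=list)
    _records: pd.DataFrame | None = None

    def p_table(self) -> pd.DataFrame:
        """Long-format SNP x ROI association table (snp_id, roi_id, beta, p)."""
        return self._records if self._records is not None else pd.DataFrame(
            columns=["snp_id", "roi_id", "beta", "p"]
        )


def snp_effect_maps(
    qts: QTMatrix,
    genotypes: GenotypeMatrix,
    contrast: Contrast,
    p_floor: float = P_FLOOR,
) -> SnpEffectMaps:
    """Step 2: for each SNP, regress every ROI's QT on the additive genotype
    (plus covariates) over the contrast's pooled cases + controls.

    SNPs that are constant (or all-missing) within the contrast subset are
    excluded with a warning and carry no map.
    """
    Y, Z = _aligned_arrays(qts, contrast)
    G = genotypes.subset_subjects(contrast.subject_ids).values
    n, n_rois = Y.shape
    maps: list[EffectMap] = []
    excluded: list[str] = []
    records: list[pd.DataFrame] = []
    n_fits = 0

    complete = ~(G == MISSING).any(axis=0)
    # fast path: SNPs with complete calls share the covariate-residualised
    # QTs, so all their fits collapse to one matrix product (FWL)
    if complete.any():
        idx = np.flatnonzero(complete)
        Gc = G[:, idx].astype(float)
        ptps = np.ptp(Gc, axis=0)
        ok = ptps > 0
        for j in idx[~ok]:
            excluded.append(str(genotypes.snp_ids[j]))
        idx = idx[ok]
        if len(idx):
            Gc = Gc[:, ok]
            C, names = _design(np.zeros(n), Z)  # [1, 0, Z] -> drop the zero col
            C = np.delete(C, 1, axis=1)
            _check_full_rank(C, [names[0]] + names[2:])
            Q, _ = np.linalg.qr(C)
            Yr = Y - Q @ (Q.T @ Y)
            Gr = Gc - Q @ (Q.T @ Gc)
            gg = np.einsum("ij,ij->j", Gr, Gr)  # per-SNP residual sum of squares
            num = Gr.T @ Yr  # SNPs x ROIs
            beta = num / gg[:, None]
            yy = np.einsum("ij,ij->j", Yr, Yr)  # per-ROI
            rss = yy[None, :] - beta * num
            df = n - C.shape[1] - 1
            if df <= 0:
                raise ValidationError(f"too few subjects ({n}) for the design")
            sigma2 = np.clip(rss, 0.0, None) / df
            se = np.sqrt(sigma2 / gg[:, None])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
            p = np.clip(2.0 * stats.t.sf(np.abs(t), df), p_floor, 1.0)
            for row, j in enumerate(idx):
                snp = str(genotypes.snp_ids[j])
                maps.append(
                    EffectMap(
                        predictor_id=snp,
                        roi_ids=qts.roi_ids,
                        values=-np.log10(p[row]),
                        signs=np.sign(beta[row]).astype(int),
                    )
                )
                records.append(
                    pd.DataFrame(
                        {"snp_id": snp, "roi_id": qts.roi_ids, "beta": beta[row], "p": p[row]}
                    )
                )
                n_fits += n_rois

    # general path: SNPs with missing calls get their own complete-case solve
    for j in np.flatnonzero(~complete):
        snp = str(genotypes.snp_ids[j])
        g = G[:, j].astype(float)
        g[G[:, j] == MISSING] = np.nan
        keep = np.isfinite(g)
        if keep.sum() < 3 or np.ptp(g[keep]) == 0:
            excluded.append(snp)
            continue
        try:
            beta, _, _, p, _, _ = _ols_multi(
                Y[keep], g[keep], Z[keep] if Z is not None and np.size(Z) else None
            )
        except (DegenerateDesignError, ValidationError):
            excluded.append(snp)
            continue
        p = np.clip(p, p_floor, 1.0)
        maps.append(
            EffectMap(
                predictor_id=snp,
                roi_ids=qts.roi_ids,
                values=-np.log10(p),
                signs=np.sign(beta).astype(int),
            )
        )
        records.append(pd.DataFrame({"snp_id": snp, "roi_id": qts.roi_ids, "beta": beta, "p": p}))
        n_fits += n_rois

    if excluded:
        log.warning(
            "contrast %s: %d SNP(s) constant or unfittable in subset, excluded: %s",
            contrast.name, len(excluded), excluded[:10],
        )
    # restore input SNP order (fast path may have reordered relative to slow path)
    order = {str(s): i for i, s in enumerate(genotypes.snp_ids)}
    sort_idx = sorted(range(len(maps)), key=lambda i: order[maps[i].predictor_id])
    maps = [maps[i] for i in sort_idx]
    records = [records[i] for i in sort_idx]
    table = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["snp_id", "roi_id", "beta", "p"])
    )
    return SnpEffectMaps(maps=maps, contrast=contrast.name, n_fits=n_fits,
                         excluded=excluded, _records=table)
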