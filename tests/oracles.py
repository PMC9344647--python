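"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the code
it validates: direct log-factorial enumeration for the exact HWE test,
explicit normal-equations algebra for OLS, and a from-the-log-likelihood
IRLS loop for logistic regression.
"""

import numpy as np
from scipy import stats
from scipy.special import gammaln


def hwe_enumeration_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p by brute-force enumeration over all
    heterozygote counts, probabilities from the closed-form expression
    n! / (nAA! nAa! naa!) * 2^nAa * nA! na! / (2n)! via log-gamma."""
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = (2 * n - n_minor - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def hwe_enumeration_probs(n: int, n_minor: int) -> np.ndarray:
    """Normalised configuration probabilities over heterozygote counts for
    fixed allele counts (same enumeration as :func:`hwe_enumeration_p`)."""
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = (2 * n - n_minor - hets) // 2
    logp = (
        -gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    return probs / probs.sum()


def ols_closed_form(y, X, coef_index=1):
    """OLS via explicit normal equations plus the exact t CDF.

    Returns (beta, se, t, p) for the coefficient at ``coef_index``;
    ``X`` must already include its intercept column.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(sigma2 * XtX_inv[coef_index, coef_index])
    t = coef[coef_index] / se
    p = 2.0 * stats.t.sf(abs(t), n - k)
    return coef[coef_index], se, t, p


def irls_logistic(y, X, tol=1e-12, maxiter=200):
    """Logistic regression by hand-rolled iteratively reweighted least
    squares on the log-likelihood; returns (coef, standard errors)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = X.T @ (W[:, None] * X)
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    info = X.T @ ((mu * (1 - mu))[:, None] * X)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def partial_corr_recursive(r_xy, r_xz, r_yz):
    """Single-covariate partial correlation by the recursive formula."""
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
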