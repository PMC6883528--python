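"""Random-intercept linear mixed model via profile REML.

The replicate-level QTL scans fit, for every (bin, SNP) pair,

    y_ir = x_i * beta + covariates + b_i + e_ir,   b_i ~ N(0, sigma_b^2),
                                                   e_ir ~ N(0, sigma_e^2),

with ``i`` indexing individuals and ``r`` replicates.  Because V =
sigma_e^2 (I + gamma Z Z') is block diagonal for a single grouping factor, the
GLS solution given the variance ratio gamma = sigma_b^2/sigma_e^2 is closed
form; REML reduces to a 1-D optimization over gamma, which makes a single fit
cheap enough for Monte-Carlo power analysis and genome-wide scans.

The Wald test on a coefficient uses a t reference with
df = N_obs - n_individuals - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class LMMResult:
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df: int
    sigma2_e: float
    sigma2_b: float
    gamma: float
    converged: bool
    method: str = "reml"


def _group_design(groups) -> tuple[np.ndarray, np.ndarray]:
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    sizes = np.bincount(codes)
    return codes, sizes


def fit_random_intercept(y, X, groups) -> LMMResult:
    """Fit a random-intercept LMM by profile REML.

    Parameters
    ----------
    y : (N,) response
    X : (N, p) fixed-effect design (include an intercept column explicitly)
    groups : (N,) individual labels
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    codes, sizes = _group_design(groups)
    n_groups = len(sizes)
    if N <= p:
        raise ValueError("more parameters than observations")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # group sums
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, codes, X)
    Sy = np.zeros(n_groups)
    np.add.at(Sy, codes, y)

    def solve(gamma: float):
        c = gamma / (1.0 + sizes * gamma)  # per-group Woodbury coefficient
        XtWX = XtX - (Sx * c[:, None]).T @ Sx
        XtWy = Xty - Sx.T @ (c * Sy)
        ytWy = yty - float(c @ (Sy**2))
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - float(beta @ XtWy), 1e-300)
        sigma2 = rss / (N - p)
        return beta, sigma2, XtWX

    def reml_neg2(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        _, sigma2, XtWX = solve(gamma)
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (N - p) * np.log(sigma2) + float(np.sum(np.log1p(sizes * gamma))) + logdet

    converged = True
    try:
        res = optimize.minimize_scalar(
            reml_neg2, bounds=(-12.0, 8.0), method="bounded",
            options={"xatol": 1e-6},
        )
        log_gamma = float(res.x)
        # compare with the gamma -> 0 boundary (pure OLS)
        if reml_neg2(-30.0) <= res.fun:
            log_gamma = -30.0
        gamma = float(np.exp(log_gamma))
        converged = bool(res.success)
    except Exception:
        gamma = 0.0
        converged = False

    beta, sigma2, XtWX = solve(gamma)
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    df = N - n_groups - 1
    tvals = beta / se
    if df > 0:
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(tvals))
    return LMMResult(
        beta=beta, se=se, tvalues=tvals, pvalues=pvals, df=max(df, 0),
        sigma2_e=float(sigma2), sigma2_b=float(sigma2 * gamma), gamma=gamma,
        converged=converged,
    )


def ols_wald(y, X, df: int | None = None):
    """Plain OLS with t-based Wald p-values; fallback when the LMM degenerates."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    N, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / max(N - p, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    dof = df if df is not None else N - p
    pvals = 2.0 * stats.t.sf(np.abs(tvals), max(dof, 1))
    return beta, se, tvals, pvals
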