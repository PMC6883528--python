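"""Shared statistical machinery.

Empirical-Bayes variance moderation (scaled-F moment matching on log sample
variances), Benjamini-Hochberg adjustment, Storey's pi0, and a covariate-
weighted BH ("IHW-lite": equal-count covariate strata, per-stratum weights
proportional to the estimated non-null proportion, normalized to mean one).
With a single stratum the weighted procedure reduces exactly to BH.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Given per-feature residual variances ``s2`` on ``df`` degrees of freedom,
    returns the prior degrees of freedom ``d0`` and prior variance ``s0^2``
    such that s2 ~ s0^2 * F(df, d0), by matching moments of log(s2).
    ``d0`` is clamped to (0, 1e6].
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return 1e6, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    rhs = evar - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * trigamma_inverse(rhs)
        d0 = float(np.clip(d0, 1e-8, 1e6))
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = 1e6
        s0_sq = np.exp(emean)
    return d0, float(s0_sq)


def moderate_variances(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior (shrunken) variances: (d0*s0^2 + df*s2)/(d0 + df)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Storey's estimate of the null proportion, truncated to [0, 1]."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        return 1.0
    pi0 = np.mean(p > lam) / (1.0 - lam)
    return float(min(max(pi0, 0.0), 1.0))


def ihw_bh(p: np.ndarray, covariate: np.ndarray, n_strata: int = 10,
           lam: float = 0.5, min_per_stratum: int = 50,
           min_weight: float = 0.1) -> np.ndarray:
    """Covariate-weighted BH adjusted p-values (IHW-lite).

    Tests are split into at most ``n_strata`` equal-count strata of the
    covariate (each at least ``min_per_stratum`` tests, else fewer strata);
    each stratum receives weight proportional to its estimated non-null
    proportion 1 - pi0 (Storey, lambda=0.5), floored at ``min_weight`` so no
    test becomes unrejectable, and normalized so the weights average one over
    tests.  Adjusted p-values are BH applied to p/w.  With one stratum, or
    when every stratum looks fully null, this is exactly BH.
    """
    p = np.asarray(p, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if p.shape != covariate.shape:
        raise ValueError("p and covariate must align")
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return np.full_like(p, np.nan)
    n_strata = max(1, min(n_strata, m // max(min_per_stratum, 1)))

    q = np.full_like(p, np.nan)
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(covariate[idx], kind="mergesort")]
    strata = np.array_split(order, n_strata)
    raw_w = np.array([1.0 - storey_pi0(p[s], lam) for s in strata])
    sizes = np.array([len(s) for s in strata], dtype=float)
    if raw_w.sum() <= 0 or n_strata == 1:
        weights = np.ones(n_strata)
    else:
        raw_w = np.maximum(raw_w, min_weight)
        weights = raw_w * m / float(np.sum(sizes * raw_w))
    weighted_p = np.full(len(p), np.nan)
    for k, s in enumerate(strata):
        weighted_p[s] = p[s] / weights[k]
    q[ok] = bh_adjust(weighted_p[ok])
    return q


def genomic_inflation(p: np.ndarray) -> dict:
    """QC summary of a scan: median p and lambda (median chi2 ratio)."""
    from scipy import stats as st

    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    if len(p) == 0:
        return {"median_p": np.nan, "lambda": np.nan, "n": 0}
    chi2 = st.chi2.isf(p, 1)
    lam = float(np.median(chi2) / st.chi2.isf(0.5, 1))
    return {"median_p": float(np.median(p)), "lambda": lam, "n": len(p)}
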