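"""Nominal-fraction sharing between QTL sets and other association scans.

The nominal fraction is the share of one study's QTL SNPs reaching p < alpha
(default 0.05) in another study's full association results — a
sub-genome-wide overlap statistic.  Significance comes from a 2x2 chi-square
against the non-QTL tested SNPs and from a permutation null drawing same-size
SNP sets from the tested universe.  For contact scans, where one SNP can be
tested against many matrix cells, each SNP is first reduced to its minimum p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def reduce_min_p(scan: pd.DataFrame) -> pd.DataFrame:
    """One row per SNP keeping the most significant p (for multi-cell scans)."""
    return (scan.sort_values("p").groupby("snp_id", as_index=False).first())


def nominal_fraction(qtl_snps, scan: pd.DataFrame, alpha: float = 0.05,
                     continuity: bool = False) -> dict:
    """Fraction of QTL SNPs nominally significant in another scan.

    Returns the fraction, the 2x2 chi-square p against non-QTL tested SNPs,
    and the underlying counts.  NaN fraction when the QTL set does not
    intersect the scan's tested SNPs.
    """
    scan = reduce_min_p(scan)
    tested = scan.set_index("snp_id")["p"]
    qtl = [s for s in set(qtl_snps) if s in tested.index]
    if not qtl:
        return {"fraction": np.nan, "chi2_p": np.nan, "n_qtl": 0,
                "n_tested": len(tested)}
    in_p = tested.loc[qtl].to_numpy()
    rest = tested.drop(index=qtl).to_numpy()
    a = int((in_p < alpha).sum())
    b = len(in_p) - a
    c = int((rest < alpha).sum())
    d = len(rest) - c
    frac = a / len(in_p)
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        chi2_p = np.nan
    else:
        _, chi2_p, _, _ = stats.chi2_contingency([[a, b], [c, d]],
                                                 correction=continuity)
    return {"fraction": float(frac), "chi2_p": float(chi2_p), "n_qtl": len(in_p),
            "n_tested": len(tested), "table": ((a, b), (c, d)),
            "background_fraction": c / max(c + d, 1)}


def bootstrap_null(universe, size: int, scan: pd.DataFrame, observed: float,
                   alpha: float = 0.05, n_perm: int = 10_000,
                   seed: int = 0) -> dict:
    """Permutation p for a nominal fraction.

    Each permutation draws ``size`` SNPs from the tested universe without
    replacement (draws are independent across permutations) and recomputes the
    nominal fraction.  Because nominal fractions are heavily tied (multiples
    of 1/size), ties between permuted and observed values count half
    (mid-p); the plain >= rule would be systematically conservative under the
    null.  p = (1 + #{perm > obs} + 0.5 #{perm == obs}) / (n_perm + 1).
    """
    scan = reduce_min_p(scan)
    tested = scan.set_index("snp_id")["p"]
    pool = np.asarray([s for s in universe if s in tested.index])
    if size > len(pool):
        raise ValueError("size exceeds the tested universe")
    pvals = tested.loc[pool].to_numpy()
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_perm)
    for t in range(n_perm):
        pick = rng.choice(len(pool), size=size, replace=False)
        fracs[t] = np.mean(pvals[pick] < alpha)
    n_gt = np.sum(fracs > observed)
    n_eq = np.sum(fracs == observed)
    p = float((1 + n_gt + 0.5 * n_eq) / (n_perm + 1))
    return {"p": p, "perm_fractions": fracs}


def external_enrichment(qtl_snps, universe, scan: pd.DataFrame,
                        ld_partners: dict | None = None, alpha: float = 0.05,
                        n_perm: int = 10_000, seed: int = 0) -> dict:
    """Enrichment of a QTL set in an external scan, with optional LD extension.

    ``ld_partners`` maps a SNP id to the SNPs in perfect LD with it in the
    same bin; the extension is applied identically to the QTL set and the
    control universe.  enrichment = (QTL nominal fraction) / (tested-universe
    nominal fraction); chi-square and permutation p as in
    :func:`nominal_fraction` / :func:`bootstrap_null`.
    """
    def extend(snps):
        out = set(snps)
        if ld_partners:
            for s in list(out):
                out.update(ld_partners.get(s, ()))
        return out

    qtl_ext = extend(qtl_snps)
    uni_ext = extend(universe)
    nf = nominal_fraction(qtl_ext, scan, alpha=alpha)
    scan_r = reduce_min_p(scan)
    tested = scan_r.set_index("snp_id")["p"]
    uni = [s for s in uni_ext if s in tested.index]
    base = float(np.mean(tested.loc[uni].to_numpy() < alpha)) if uni else np.nan
    enrich = nf["fraction"] / base if base and np.isfinite(base) and base > 0 else np.nan
    boot = (bootstrap_null(uni, nf["n_qtl"], scan_r, nf["fraction"], alpha=alpha,
                           n_perm=n_perm, seed=seed)
            if nf["n_qtl"] and uni else {"p": np.nan})
    return {"enrichment": float(enrich) if np.isfinite(enrich) else np.nan,
            "fraction_qtl": nf["fraction"], "fraction_universe": base,
            "chi2_p": nf["chi2_p"], "boot_p": boot["p"]}
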