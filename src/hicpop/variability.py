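"""Inter-individual variability of 3D-chromatin phenotypes.

Replicate-level bin tracks (or BNBC-corrected matrix cells) are scanned with a
one-way fixed-effects model (individual as factor).  For bin tracks the
residual variances are shrunk with an empirical-Bayes scaled-F prior
(limma-style moderated F); for matrix cells a plain F test is combined with a
covariate-weighted BH using anchor distance (IHW-lite).  Bootstrap resampling
of replicate labels gives an empirical FDR; Spearman correlation against
external per-individual tracks, with individual-label permutation nulls, links
variable regions to other molecular phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contact import BinCovariates
from .features import DI_STRONG_BIAS_THRESHOLD, FIRE_Z_THRESHOLD
from .stats import bh_adjust, fit_f_dist, ihw_bh, moderate_variances

#: metric-specific SV exclusion flank, in bp
SV_FLANK = {"FIRE": 200_000, "INS": 400_000, "DI": 2_000_000, "PC1": 0}
UNRELIABLE_FLANK = 200_000


@dataclass
class ModeratedFResult:
    ms_between: np.ndarray
    s2: np.ndarray
    s2_moderated: np.ndarray
    f: np.ndarray
    p: np.ndarray
    q: np.ndarray
    d0: float
    s0_sq: float
    df_between: int
    df_within: float


@dataclass
class VariableRegionSet:
    regions: list[tuple[int, int]]  # inclusive bin intervals
    metric: str
    fdr: float
    significant_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _bins_overlapping(intervals, bin_size: int, n_bins: int, flank: int = 0) -> np.ndarray:
    """Boolean mask of bins overlapping any (start, end) bp interval +/- flank."""
    hit = np.zeros(n_bins, dtype=bool)
    for start, end in intervals:
        lo = max(0, (start - 1 - flank) // bin_size)
        hi = min(n_bins - 1, (end - 1 + flank) // bin_size)
        hit[lo: hi + 1] = True
    return hit


def select_testable_bins(metric: str, tracks: np.ndarray, cov: BinCovariates,
                         bin_size: int, sv_intervals=None, exclude_intervals=None,
                         sv_min_size: int = 10_000) -> np.ndarray:
    """Boolean testability mask for one metric.

    ``tracks`` is replicates x bins of the metric's replicate-level scores
    (FIRE: z-scores; DI: raw DI; INS: raw INS in [0,1]; PC1: ignored).
    Inclusion: FIRE needs a FIRE call in any replicate, DI needs
    |DI| > 10.82757 in any replicate, INS needs a per-replicate z-scored score
    < -1 in any replicate; PC1 has no metric filter.  Exclusion: bins with a
    zero covariate and bins within 200 kb of them; configured excluded regions
    (e.g. the MHC); bins within the metric-specific flank of large structural
    variants (> 10 kb).
    """
    metric = metric.upper()
    if metric not in SV_FLANK:
        raise ValueError(f"unknown metric {metric!r}")
    n_bins_ = cov.n_bins
    mask = np.ones(n_bins_, dtype=bool)

    if metric == "FIRE":
        mask &= np.nanmax(np.where(np.isfinite(tracks), tracks, -np.inf), axis=0) > FIRE_Z_THRESHOLD
    elif metric == "DI":
        with np.errstate(invalid="ignore"):
            mask &= np.any(np.abs(tracks) > DI_STRONG_BIAS_THRESHOLD, axis=0)
    elif metric == "INS":
        z = np.full_like(np.asarray(tracks, dtype=float), np.nan)
        for r in range(tracks.shape[0]):
            row = tracks[r]
            ok = np.isfinite(row)
            if ok.sum() > 1 and row[ok].std() > 0:
                z[r, ok] = (row[ok] - row[ok].mean()) / row[ok].std()
        mask &= np.any(z < -1.0, axis=0)

    unreliable = cov.unreliable
    flank_bins = UNRELIABLE_FLANK // bin_size
    near = unreliable.copy()
    for b in np.flatnonzero(unreliable):
        near[max(0, b - flank_bins): b + flank_bins + 1] = True
    mask &= ~near

    if exclude_intervals:
        mask &= ~_bins_overlapping(exclude_intervals, bin_size, n_bins_)
    if sv_intervals:
        large = [(s, e) for s, e in sv_intervals if e - s + 1 > sv_min_size]
        if large:
            mask &= ~_bins_overlapping(large, bin_size, n_bins_, flank=SV_FLANK[metric])
    return mask


def _oneway_anova(values: np.ndarray, codes: np.ndarray, k: int):
    """Vectorized one-way ANOVA across columns: values is samples x features."""
    n = values.shape[0]
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for g in range(k):
        rows = codes == g
        ng = rows.sum()
        gm = values[rows].mean(axis=0)
        ss_between += ng * (gm - grand) ** 2
        ss_within += ((values[rows] - gm) ** 2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    return ss_between / df_b, ss_within / max(df_w, 1), df_b, df_w


def merge_adjacent_bins(bins: np.ndarray) -> list[tuple[int, int]]:
    """Merge sorted bin indices into maximal runs of consecutive bins."""
    bins = np.sort(np.asarray(bins, dtype=int))
    if len(bins) == 0:
        return []
    splits = np.flatnonzero(np.diff(bins) > 1) + 1
    return [(int(run[0]), int(run[-1])) for run in np.split(bins, splits)]


def moderated_f_scan(tracks: np.ndarray, individuals, metric: str = "",
                     fdr: float = 0.1, mask: np.ndarray | None = None,
                     force_d0: float | None = None):
    """Moderated-F scan for between-individual variability of a bin track.

    ``tracks`` is replicate-samples x bins; ``individuals`` the per-sample
    individual labels.  Residual variances are shrunk with the scaled-F
    empirical-Bayes prior; the moderated F of MS_between over the shrunken
    variance is referred to F(k-1, d0 + df_within); BH at ``fdr``; adjacent
    significant bins merge into regions.  ``force_d0`` pins the prior df
    (0 reproduces the ordinary one-way ANOVA F).
    """
    tracks = np.asarray(tracks, dtype=float)
    inds, codes = np.unique(np.asarray(individuals), return_inverse=True)
    k = len(inds)
    if k < 2 or tracks.shape[0] < 2 * 2:
        raise ValueError("need >= 2 replicates for >= 2 individuals")
    n_bins_ = tracks.shape[1]
    if mask is None:
        mask = np.ones(n_bins_, dtype=bool)
    testable = mask & np.all(np.isfinite(tracks), axis=0)

    vals = tracks[:, testable]
    ms_between, s2, df_b, df_w = _oneway_anova(vals, codes, k)
    if force_d0 is None:
        d0, s0_sq = fit_f_dist(s2, df_w)
    elif force_d0 == 0:
        d0, s0_sq = 0.0, 1.0
    else:
        d0 = force_d0
        _, s0_sq = fit_f_dist(s2, df_w)
    if d0 == 0:
        s2_mod = s2.copy()
        denom_df = df_w
    else:
        s2_mod = moderate_variances(s2, df_w, d0, s0_sq)
        denom_df = d0 + df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ms_between / s2_mod
    p = stats.f.sf(fstat, df_b, denom_df)
    q = bh_adjust(p)

    full = {name: np.full(n_bins_, np.nan) for name in
            ("ms_between", "s2", "s2_moderated", "f", "p", "q")}
    for name, arr in zip(("ms_between", "s2", "s2_moderated", "f", "p", "q"),
                         (ms_between, s2, s2_mod, fstat, p, q)):
        full[name][testable] = arr
    res = ModeratedFResult(
        ms_between=full["ms_between"], s2=full["s2"],
        s2_moderated=full["s2_moderated"], f=full["f"], p=full["p"], q=full["q"],
        d0=float(d0), s0_sq=float(s0_sq), df_between=df_b, df_within=float(df_w),
    )
    sig = np.flatnonzero(np.where(np.isfinite(full["q"]), full["q"], 1.0) <= fdr)
    regions = VariableRegionSet(
        regions=merge_adjacent_bins(sig), metric=metric, fdr=fdr, significant_bins=sig)
    return res, regions


def empirical_fdr(tracks: np.ndarray, individuals, n_boot: int = 1000,
                  seed: int = 0, fdr: float = 0.1,
                  mask: np.ndarray | None = None) -> dict:
    """Bootstrap empirical FDR for the moderated-F scan.

    Replicate columns are resampled with replacement and reassigned to the
    fixed individual layout, breaking the true individual grouping; the
    empirical FDR is the mean significant-region count over bootstraps divided
    by the observed count (NaN when the observed count is zero).
    """
    tracks = np.asarray(tracks, dtype=float)
    _, regions = moderated_f_scan(tracks, individuals, fdr=fdr, mask=mask)
    observed = len(regions.regions)
    rng = np.random.default_rng(seed)
    n_samples = tracks.shape[0]
    boot_counts = np.zeros(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_samples, size=n_samples)
        _, boot_regions = moderated_f_scan(tracks[pick], individuals, fdr=fdr, mask=mask)
        boot_counts[b] = len(boot_regions.regions)
    efdr = float(boot_counts.mean() / observed) if observed > 0 else np.nan
    return {"observed": observed, "mean_boot": float(boot_counts.mean()),
            "empirical_fdr": efdr, "boot_counts": boot_counts}


def cell_variability_scan(cell_values: np.ndarray, individuals,
                          distances: np.ndarray, bin_size: int = 40_000,
                          max_distance: int = 28_000_000,
                          fdr: float = 0.1) -> pd.DataFrame:
    """Between-individual variability of BNBC-corrected matrix cells.

    ``cell_values`` is samples x cells, ``distances`` the per-cell anchor
    distance in bins.  Cells beyond ``max_distance`` are excluded.  Per cell:
    one-way F test of the individual effect; IHW-lite FDR with distance as the
    covariate; and a balanced-design variance decomposition into between- and
    within-individual components.
    """
    cell_values = np.asarray(cell_values, dtype=float)
    distances = np.asarray(distances)
    keep = distances * bin_size < max_distance  # strictly below the cap
    vals = cell_values[:, keep]
    inds, codes = np.unique(np.asarray(individuals), return_inverse=True)
    k = len(inds)
    ms_between, ms_within, df_b, df_w = _oneway_anova(vals, codes, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    p = np.where(ms_within > 0,
                 stats.f.sf(f, df_b, df_w),
                 np.where(ms_between > 0, 0.0, 1.0))
    q = ihw_bh(p, distances[keep].astype(float))
    # method-of-moments variance components (balanced replicates)
    r = vals.shape[0] / k
    var_between = np.maximum((ms_between - ms_within) / r, 0.0)
    out = pd.DataFrame({
        "cell": np.flatnonzero(keep),
        "distance_bins": distances[keep],
        "f": f, "p": p, "q": q,
        "var_between": var_between,
        "var_within": ms_within,
    })
    out["significant"] = out["q"] <= fdr
    return out


def correlate_with_tracks(regions: VariableRegionSet, feature: np.ndarray,
                          external: np.ndarray, n_perm: int = 10_000,
                          seed: int = 0) -> dict:
    """Spearman correlation of a 3D feature with an external per-individual track.

    ``feature`` and ``external`` are individuals x bins.  Each variable region
    collapses to its bin with the strongest mean |external| signal; per bin the
    Spearman rho across individuals is computed; the permutation null shuffles
    individual labels of the external data; the two-sided permutation p
    compares |median rho|.
    """
    n_ind = feature.shape[0]
    if n_ind < 4:
        raise ValueError("need >= 4 individuals for rank correlation")
    if not regions.regions:
        return {"bins": [], "rho": np.array([]), "p_perm": np.nan}
    strength = np.abs(external).mean(axis=0)
    bins = [int(lo + np.argmax(strength[lo: hi + 1])) for lo, hi in regions.regions]

    # Spearman = Pearson on ranks; rank once, then permutations are row shuffles
    def _norm_ranks(x):
        r = np.apply_along_axis(stats.rankdata, 0, x)
        r -= r.mean(axis=0)
        denom = np.sqrt((r**2).sum(axis=0))
        denom[denom == 0] = np.nan
        return r / denom

    fr = _norm_ranks(feature[:, bins])
    er = _norm_ranks(external[:, bins])

    def rhos(perm=None):
        e = er if perm is None else er[perm]
        return (fr * e).sum(axis=0)

    obs = rhos()
    obs_med = np.nanmedian(obs)
    rng = np.random.default_rng(seed)
    perm_meds = np.empty(n_perm)
    for t in range(n_perm):
        perm_meds[t] = np.nanmedian(rhos(rng.permutation(n_ind)))
    # rank-based Spearman medians are discrete; ties count half (mid-p)
    n_gt = np.sum(np.abs(perm_meds) > abs(obs_med))
    n_eq = np.sum(np.abs(perm_meds) == abs(obs_med))
    p = (1 + n_gt + 0.5 * n_eq) / (n_perm + 1)
    return {"bins": bins, "rho": obs, "median_rho": float(obs_med),
            "p_perm": float(p), "perm_medians": perm_meds}


def reproducibility_summary(tracks: np.ndarray, individuals) -> pd.DataFrame:
    """Pearson correlations of all replicate pairs, labeled within/between individual.

    Returns a long table with one row per sample pair; attach the rank-sum
    comparison via :func:`within_between_test`.
    """
    tracks = np.asarray(tracks, dtype=float)
    individuals = np.asarray(individuals)
    n = tracks.shape[0]
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            ok = np.isfinite(tracks[a]) & np.isfinite(tracks[b])
            r = np.corrcoef(tracks[a, ok], tracks[b, ok])[0, 1] if ok.sum() > 1 else np.nan
            rows.append({"a": a, "b": b,
                         "group": "within" if individuals[a] == individuals[b] else "between",
                         "pearson": r})
    return pd.DataFrame(rows)


def matrix_reproducibility_summary(matrices: dict, individuals: dict) -> pd.DataFrame:
    """Per-distance replicate-pair Pearson correlations for contact matrices."""
    ids = list(matrices)
    n = matrices[ids[0]].n_bins
    rows = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            group = "within" if individuals[a] == individuals[b] else "between"
            for d in range(1, n):
                va = np.diagonal(matrices[a].values, offset=d)
                vb = np.diagonal(matrices[b].values, offset=d)
                ok = np.isfinite(va) & np.isfinite(vb)
                if ok.sum() > 2 and va[ok].std() > 0 and vb[ok].std() > 0:
                    r = np.corrcoef(va[ok], vb[ok])[0, 1]
                    rows.append({"a": a, "b": b, "distance": d,
                                 "group": group, "pearson": r})
    return pd.DataFrame(rows)


def within_between_test(pairs: pd.DataFrame) -> dict:
    """Two-sided rank-sum comparison of within- vs between-individual correlations."""
    within = pairs.loc[pairs.group == "within", "pearson"].dropna()
    between = pairs.loc[pairs.group == "between", "pearson"].dropna()
    if len(within) == 0 or len(between) == 0 or \
            (within.nunique() == 1 and between.nunique() == 1 and
             within.iloc[0] == between.iloc[0]):
        return {"p": np.nan, "median_within": float(within.median()) if len(within) else np.nan,
                "median_between": float(between.median()) if len(between) else np.nan}
    stat = stats.mannwhitneyu(within, between, alternative="two-sided")
    return {"p": float(stat.pvalue), "median_within": float(within.median()),
            "median_between": float(between.median())}
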