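"""Linear-mixed-model QTL mapping of 3D-chromatin phenotypes.

Replicate-level FIRE / DI / INS scores (or BNBC-corrected matrix cells) are
regressed on SNP dosage with a per-individual random intercept; the Wald test
on the genotype coefficient uses a t reference with df = N_obs -
n_individuals - 1.  Discovery calls use BH (bin phenotypes; DI split into
upstream- and downstream-biased classes) or distance-weighted BH (contact
cells) at FDR 0.2, keep the best SNP per target, and are validated in held-out
individuals against a resampled (bin, SNP) null.  A Monte-Carlo power module
simulates the full design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import bin_of_position
from .lmm import fit_random_intercept, ols_wald
from .stats import bh_adjust, genomic_inflation, ihw_bh


@dataclass
class PowerConfig:
    """Design of one Monte-Carlo power cell."""

    maf: float = 0.25
    beta: float = 1.0
    subject_sd: float = 0.5
    residual_sd: float = 0.5
    n_subjects: int = 11
    n_replicates: int = 2
    n_sim: int = 1000
    alpha: float = 0.05
    cell_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def select_test_snps(genotypes: pd.DataFrame, bin_mask: np.ndarray,
                     discovery_ids: list[str], bin_size: int,
                     hindiii_excl=frozenset(), min_maf: float = 0.05) -> pd.DataFrame:
    """Filter SNPs to the testable set and collapse perfect-LD groups per bin.

    Keeps biallelic single-nucleotide variants outside the HindIII-polymorphism
    exclusion list, inside testable bins, with MAF >= ``min_maf`` and both
    alleles present in >= 2 discovery individuals; within each bin, groups of
    SNPs whose discovery dosage vectors are identical (or exactly opposite,
    i.e. a global allele swap) collapse to the smallest-position tag SNP.
    """
    if not discovery_ids:
        raise ValueError("empty discovery set")
    g = genotypes.copy()
    g = g[(g["ref"].str.len() == 1) & (g["alt"].str.len() == 1)]
    if hindiii_excl:
        g = g[~g["pos"].isin(set(hindiii_excl))]
    g["bin"] = [(int(p) - 1) // bin_size for p in g["pos"]]
    in_mask = np.fromiter((bool(bin_mask[b]) for b in g["bin"]),
                          dtype=bool, count=len(g))
    g = g.loc[in_mask]

    D = g[discovery_ids].to_numpy(dtype=float)
    obs = D >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, D, 0).sum(axis=1) / (2 * np.maximum(obs.sum(axis=1), 1))
    maf = np.minimum(freq, 1 - freq)
    has_alt = ((D >= 1) & obs).sum(axis=1) >= 2
    has_ref = ((D <= 1) & obs).sum(axis=1) >= 2
    g = g[(maf >= min_maf) & has_alt & has_ref]

    # perfect-LD collapse per bin (identical or flipped dosages on discovery)
    g = g.sort_values(["bin", "pos"]).reset_index(drop=True)
    g["ld_group"] = -1
    g["is_tag"] = False
    next_gid = 0
    for _, sub in g.groupby("bin", sort=True):
        seen: dict[tuple, int] = {}
        for ridx in sub.index:
            vec = tuple(int(v) for v in g.loc[ridx, discovery_ids])
            flip = tuple((2 - v) if v >= 0 else v for v in vec)
            key = min(vec, flip)
            if key not in seen:
                seen[key] = next_gid
                g.loc[ridx, "is_tag"] = True  # first by position = smallest
                next_gid += 1
            g.loc[ridx, "ld_group"] = seen[key]
    return g


def lmm_scan(pheno: np.ndarray, sample_individuals, snps: pd.DataFrame,
             dosage_ids: list[str], tags_only: bool = True) -> pd.DataFrame:
    """LMM association scan of a replicate-level bin phenotype against test SNPs.

    ``pheno`` is samples x bins (replicate-level scores); ``sample_individuals``
    the per-sample individual label; ``snps`` a testable-SNP table from
    :func:`select_test_snps` with a ``bin`` column; ``dosage_ids`` names the
    genotype columns (the discovery individuals).  Returns one row per
    (bin, SNP) pair with beta, p and fit metadata.
    """
    pheno = np.asarray(pheno, dtype=float)
    sample_individuals = np.asarray(sample_individuals)
    rows = []
    snp_iter = snps[snps["is_tag"]] if (tags_only and "is_tag" in snps) else snps
    for _, snp in snp_iter.iterrows():
        b = int(snp["bin"])
        if b >= pheno.shape[1]:
            continue
        y_all = pheno[:, b]
        dose_of = {ind: int(snp[ind]) for ind in dosage_ids}
        use = np.array([
            (ind in dose_of) and dose_of[ind] >= 0 and np.isfinite(y_all[k])
            for k, ind in enumerate(sample_individuals)])
        if use.sum() < 6:
            continue
        y = y_all[use]
        groups = sample_individuals[use]
        x = np.array([dose_of[ind] for ind in groups], dtype=float)
        if np.ptp(x) == 0:
            continue  # genotype constant among usable individuals
        X = np.column_stack([np.ones_like(x), x])
        try:
            fit = fit_random_intercept(y, X, groups)
            beta, se, p = fit.beta[1], fit.se[1], fit.pvalues[1]
            method = "reml"
            if not fit.converged:
                raise RuntimeError
        except Exception:
            bvec, sevec, _, pvec = ols_wald(y, X)
            beta, se, p = bvec[1], sevec[1], pvec[1]
            method = "ols_fallback"
        rows.append({"bin": b, "snp_id": snp["snp_id"], "pos": int(snp["pos"]),
                     "beta": float(beta), "se": float(se), "p": float(p),
                     "n_obs": int(use.sum()), "method": method})
    return pd.DataFrame(rows)


def classify_di_bins(di_tracks: np.ndarray) -> np.ndarray:
    """Per-bin DI class from discovery individuals' DI: sign of the max-|DI| value.

    Returns an array of "up" / "down" / "na" per bin.
    """
    di_tracks = np.asarray(di_tracks, dtype=float)
    out = np.full(di_tracks.shape[1], "na", dtype=object)
    for b in range(di_tracks.shape[1]):
        col = di_tracks[:, b]
        ok = np.isfinite(col)
        if not ok.any():
            continue
        extreme = col[ok][np.argmax(np.abs(col[ok]))]
        out[b] = "up" if extreme > 0 else "down"
    return out


def call_qtls(scan: pd.DataFrame, phenotype: str, fdr: float = 0.2,
              di_classes: np.ndarray | None = None) -> pd.DataFrame:
    """FDR-controlled QTL calls: best SNP per bin among BH-significant tests.

    For DI the scan is split by the bin's bias class (upstream vs downstream)
    and BH is applied within each class.  Ties on p break by smaller position.
    """
    if scan.empty:
        return scan.assign(q=pd.Series(dtype=float), phenotype=phenotype)
    scan = scan.copy()
    if phenotype.upper() == "DI":
        if di_classes is None:
            raise ValueError("DI calls need per-bin bias classes")
        scan["di_class"] = [di_classes[b] for b in scan["bin"]]
        parts = []
        for cls, sub in scan.groupby("di_class"):
            if cls == "na":
                continue
            sub = sub.copy()
            sub["q"] = bh_adjust(sub["p"].to_numpy())
            parts.append(sub)
        scan = pd.concat(parts) if parts else scan.assign(q=np.nan)
    else:
        scan["q"] = bh_adjust(scan["p"].to_numpy())
    sig = scan[scan["q"] <= fdr]
    if sig.empty:
        return sig.assign(phenotype=phenotype)
    best = (sig.sort_values(["p", "pos"]).groupby("bin", as_index=False).first())
    best["phenotype"] = phenotype
    best["direction"] = np.sign(best["beta"])
    return best.reset_index(drop=True)


def cqtl_scan(cell_values: np.ndarray, cells: list[tuple[int, int]],
              sample_individuals, snps: pd.DataFrame, dosage_ids: list[str],
              fdr: float = 0.2, bin_size: int = 40_000,
              max_distance: int = 28_000_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contact-QTL scan over variable matrix cells.

    A SNP is tested against a cell when it lies in either anchor bin.  Per
    test: random-intercept LMM of the BNBC value on dosage; FDR via
    distance-weighted BH at ``fdr``; best SNP per cell, and among perfect-LD
    SNPs across the two anchor bins the leftmost is kept.  Returns
    (all tests, calls).
    """
    pheno = np.asarray(cell_values, dtype=float)
    sample_individuals = np.asarray(sample_individuals)
    snp_by_bin: dict[int, list[int]] = {}
    snp_tab = snps[snps["is_tag"]] if "is_tag" in snps else snps
    for ridx, snp in snp_tab.iterrows():
        snp_by_bin.setdefault(int(snp["bin"]), []).append(ridx)
    rows = []
    for c_idx, (i, j) in enumerate(cells):
        if (j - i) * bin_size >= max_distance:
            continue
        for ridx in snp_by_bin.get(i, []) + snp_by_bin.get(j, []):
            snp = snp_tab.loc[ridx]
            y_all = pheno[:, c_idx]
            dose_of = {ind: int(snp[ind]) for ind in dosage_ids}
            use = np.array([
                (ind in dose_of) and dose_of[ind] >= 0 and np.isfinite(y_all[k])
                for k, ind in enumerate(sample_individuals)])
            if use.sum() < 6:
                continue
            y = y_all[use]
            groups = sample_individuals[use]
            x = np.array([dose_of[ind] for ind in groups], dtype=float)
            if np.ptp(x) == 0:
                continue
            X = np.column_stack([np.ones_like(x), x])
            try:
                fit = fit_random_intercept(y, X, groups)
                beta, p = fit.beta[1], fit.pvalues[1]
            except Exception:
                bvec, _, _, pvec = ols_wald(y, X)
                beta, p = bvec[1], pvec[1]
            dose_key = tuple(dose_of[i2] for i2 in dosage_ids)
            flip_key = tuple((2 - v) if v >= 0 else v for v in dose_key)
            rows.append({"cell": c_idx, "anchor_i": i, "anchor_j": j,
                         "distance_bins": j - i, "snp_id": snp["snp_id"],
                         "pos": int(snp["pos"]),
                         "ld_key": min(dose_key, flip_key),
                         "beta": float(beta), "p": float(p)})
    tests = pd.DataFrame(rows)
    if tests.empty:
        return tests, tests
    tests["q"] = ihw_bh(tests["p"].to_numpy(), tests["distance_bins"].to_numpy(dtype=float))
    sig = tests[tests["q"] <= fdr]
    if sig.empty:
        return tests, sig.drop(columns=["ld_key"], errors="ignore")
    # best SNP per cell; among that cell's perfect-LD partners (identical or
    # globally flipped dosage vectors across the two anchor bins) report the
    # leftmost SNP of the group
    best_rows = []
    for c_idx, sub in sig.groupby("cell"):
        top = sub.sort_values(["p", "pos"]).iloc[0].copy()
        partners = tests[(tests["cell"] == c_idx) & (tests["ld_key"] == top["ld_key"])]
        leftmost = partners.sort_values("pos").iloc[0]
        top["snp_id"], top["pos"] = leftmost["snp_id"], leftmost["pos"]
        best_rows.append(top)
    best = pd.DataFrame(best_rows).drop(columns=["ld_key"])
    best["phenotype"] = "CONTACT"
    return tests.drop(columns=["ld_key"]), best.reset_index(drop=True)


def validate_qtls(qtls: pd.DataFrame, heldout_pheno: np.ndarray,
                  heldout_individuals, genotypes: pd.DataFrame,
                  heldout_ids: list[str], universe: pd.DataFrame,
                  n_perm: int = 1000, seed: int = 0) -> dict:
    """Held-out validation of a QTL set.

    Pools, over QTLs and held-out samples, the per-bin z-scored phenotype
    against dosage oriented by the discovery direction of effect; the observed
    pooled slope is compared with slopes of ``n_perm`` random same-size
    (bin, SNP) draws from the testable universe (oriented by their own
    discovery betas).  Missing dosages (coded -1) are dropped.
    """
    if qtls.empty:
        raise ValueError("nothing to validate")
    heldout_pheno = np.asarray(heldout_pheno, dtype=float)
    heldout_individuals = np.asarray(heldout_individuals)
    if not set(heldout_ids):
        raise ValueError("no held-out individuals")
    geno = genotypes.set_index("snp_id")

    def pooled_slope(pairs: pd.DataFrame):
        xs, ys = [], []
        for _, row in pairs.iterrows():
            b = int(row["bin"])
            snp = geno.loc[row["snp_id"]]
            y_all = heldout_pheno[:, b]
            ok = np.isfinite(y_all)
            if ok.sum() < 3:
                continue
            col = y_all[ok]
            sd = col.std()
            if sd == 0:
                continue
            z = (col - col.mean()) / sd
            for val, ind in zip(z, heldout_individuals[ok]):
                d = int(snp[ind])
                if d < 0:
                    continue
                x = d if row["beta"] >= 0 else 2 - d
                xs.append(x)
                ys.append(val)
        if len(xs) < 3 or np.ptp(xs) == 0:
            return np.nan, np.nan
        fit = stats.linregress(xs, ys)
        return float(fit.slope), float(fit.pvalue)

    obs_slope, obs_p = pooled_slope(qtls)
    rng = np.random.default_rng(seed)
    uni_bins = universe["bin"].unique()
    perm_slopes = np.empty(n_perm)
    for t in range(n_perm):
        bins = rng.choice(uni_bins, size=min(len(qtls), len(uni_bins)), replace=False)
        picks = []
        for b in bins:
            cand = universe[universe["bin"] == b]
            picks.append(cand.iloc[rng.integers(0, len(cand))])
        perm_slopes[t], _ = pooled_slope(pd.DataFrame(picks))
    finite = np.isfinite(perm_slopes)
    boot_p = float((1 + np.sum(perm_slopes[finite] >= obs_slope)) / (finite.sum() + 1))
    return {"slope": obs_slope, "lm_p": obs_p, "boot_p": boot_p,
            "perm_slopes": perm_slopes}


def aggregate_submatrices(targets: pd.DataFrame, matrices: dict,
                          genotypes: pd.DataFrame, individual_ids: list[str],
                          flank_bins: int = 25) -> dict:
    """Genotype-contrast difference maps averaged over QTL targets.

    ``targets`` needs columns anchor_i, anchor_j (or bin twice), snp_id, beta.
    Dosages are recoded so 2 = homozygous for the phenotype-increasing allele.
    Per target and genotype class the mean submatrix (anchor +/- flank) over
    individuals is taken; per-individual submatrices containing missing values
    are discarded; contrasts (2-1) and (1-0) are averaged across targets.
    """
    geno = genotypes.set_index("snp_id")
    size = 2 * flank_bins + 1
    sums = {"d21": np.zeros((size, size)), "d10": np.zeros((size, size))}
    counts = {"d21": 0, "d10": 0}
    skipped_edge = 0
    for _, t in targets.iterrows():
        i = int(t.get("anchor_i", t.get("bin")))
        j = int(t.get("anchor_j", t.get("bin")))
        any_m = next(iter(matrices.values()))
        n = any_m.n_bins
        if i - flank_bins < 0 or j + flank_bins >= n:
            skipped_edge += 1
            continue
        snp = geno.loc[t["snp_id"]]
        means = {}
        for cls in (0, 1, 2):
            subs = []
            for ind in individual_ids:
                d = int(snp[ind])
                if d < 0:
                    continue
                if t["beta"] < 0:
                    d = 2 - d
                if d != cls:
                    continue
                sub = matrices[ind].values[i - flank_bins: i + flank_bins + 1,
                                           j - flank_bins: j + flank_bins + 1]
                if np.isnan(sub).any():
                    continue
                subs.append(sub)
            if subs:
                means[cls] = np.mean(subs, axis=0)
        if 2 in means and 1 in means:
            sums["d21"] += means[2] - means[1]
            counts["d21"] += 1
        if 1 in means and 0 in means:
            sums["d10"] += means[1] - means[0]
            counts["d10"] += 1
    return {
        "d21": sums["d21"] / counts["d21"] if counts["d21"] else None,
        "d10": sums["d10"] / counts["d10"] if counts["d10"] else None,
        "n_d21": counts["d21"], "n_d10": counts["d10"],
        "skipped_edge": skipped_edge,
    }


def power_simulation(cfg: PowerConfig) -> float:
    """Monte-Carlo power of the replicate-level LMM Wald test.

    Per simulation: per-subject dosage = sum of two Bernoulli(maf) draws;
    response = cell_mean + beta*dosage + subject intercept (sd subject_sd) +
    residual (sd residual_sd) with ``n_replicates`` per subject; the same LMM
    as the QTL scans is fit and the genotype null rejected at ``alpha``.
    Simulations with a monomorphic genotype draw are redrawn.
    """
    rng = np.random.default_rng(cfg.seed)
    n, r = cfg.n_subjects, cfg.n_replicates
    groups = np.repeat(np.arange(n), r)
    X0 = np.ones(n * r)
    rejections = 0
    for _ in range(cfg.n_sim):
        for _attempt in range(1000):
            dose = rng.binomial(1, cfg.maf, n) + rng.binomial(1, cfg.maf, n)
            if np.ptp(dose) > 0:
                break
        else:
            raise RuntimeError("could not draw a polymorphic genotype")
        subj = rng.normal(0, cfg.subject_sd, n)
        y = (cfg.cell_mean + cfg.beta * dose[groups] + subj[groups]
             + rng.normal(0, cfg.residual_sd, n * r))
        X = np.column_stack([X0, dose[groups].astype(float)])
        fit = fit_random_intercept(y, X, groups)
        if fit.pvalues[1] < cfg.alpha:
            rejections += 1
    return rejections / cfg.n_sim


def scan_inflation(scan: pd.DataFrame) -> dict:
    """Genomic-inflation QC (median p, lambda) of a scan's p-values."""
    return genomic_inflation(scan["p"].to_numpy() if len(scan) else np.array([]))
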