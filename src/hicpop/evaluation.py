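"""End-to-end evaluation pipelines on the synthetic cohort.

Each function simulates a cohort with planted truth, runs the relevant slice
of the analysis stack, and measures how well the truth is recovered.  These
are the package's own benchmarks: type-I calibration of the QTL machinery,
recall/false-discovery of planted FIRE-, INS- and contact-QTLs, compartment
and TAD recovery, batch-shift removal, and null calibration of the
permutation tooling.

Problem sizes default to a 200-bin (8-Mb) chromosome with 11 individuals and
2 replicates — large enough for every window-based phenotype, small enough to
run hundreds of seeds on a desk machine.  Planted QTL effects default to
about 1.5 phenotype standard deviations per allele dose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bnbc import BandSlice, bnbc_correct, extract_bands
from .contact import oe_transform
from .features import call_tads, compartment_pc1, directionality_index, \
    fire_scores, insulation_score, local_cis_counts
from .lmm import fit_random_intercept
from .qtl import call_qtls, cqtl_scan, lmm_scan
from .synthetic import QTLEffect, SimConfig, default_truth, \
    simulate_bin_covariates, simulate_cohort_matrices

#: planted QTL effect sizes (natural-log count-scale factor per alt dose)
FIRE_QTL_BETA = 0.35
INS_QTL_BETA = -0.4
CONTACT_QTL_BETA = 0.5


def _bin_snps(cfg: SimConfig, bins, rng: np.random.Generator,
              maf_range=(0.2, 0.5)) -> pd.DataFrame:
    """One polymorphic test SNP per requested bin (positions at bin centers)."""
    recs = []
    mafs = rng.uniform(*maf_range, size=len(bins))
    for k, (b, m) in enumerate(zip(bins, mafs)):
        dos = rng.binomial(1, m, cfg.n_individuals) + rng.binomial(1, m, cfg.n_individuals)
        for _ in range(100):
            if ((dos >= 1).sum() >= 2) and ((dos <= 1).sum() >= 2):
                break
            dos = rng.binomial(1, m, cfg.n_individuals) + \
                rng.binomial(1, m, cfg.n_individuals)
        rec = {"snp_id": f"s{k:04d}", "chrom": "chrS",
               "pos": int(b) * cfg.bin_size + cfg.bin_size // 2,
               "ref": "A", "alt": "G", "bin": int(b), "is_tag": True}
        for i, ind in enumerate(cfg.individuals):
            rec[ind] = int(dos[i])
        recs.append(rec)
    return pd.DataFrame(recs)


def _pick_separated(rng: np.random.Generator, pool, n: int, min_gap: int):
    chosen: list[int] = []
    for b in rng.permutation(np.asarray(pool)):
        if all(abs(int(b) - c) >= min_gap for c in chosen):
            chosen.append(int(b))
        if len(chosen) == n:
            break
    return np.array(chosen, dtype=int)


def fire_qtl_recovery(seed: int, beta: float = FIRE_QTL_BETA,
                      n_planted: int = 12, n_null: int = 48,
                      fdr: float = 0.2) -> dict:
    """Plant FIRE-QTLs, run counts -> FIRE z -> LMM scan -> calls; score recovery.

    Null SNP bins are kept >= 6 bins from planted bins because a planted
    effect spans the 5-bin local-contact window of its target.
    """
    rng = np.random.default_rng(seed + 10_000)
    cfg = SimConfig(n_individuals=11, seed=seed, chrom_length=8_000_000)
    truth = default_truth(cfg, batch_shift=0.0)
    n = cfg.n_bins
    planted = _pick_separated(rng, np.arange(10, n - 10), n_planted, min_gap=6)
    pool = [b for b in range(10, n - 10)
            if all(abs(b - p) >= 6 for p in planted)]
    null = _pick_separated(rng, pool, n_null, min_gap=1)
    cand = np.concatenate([planted, null])
    geno = _bin_snps(cfg, cand, rng)
    truth.qtl_effects = [QTLEffect(f"s{k:04d}", "FIRE", int(planted[k]), beta)
                         for k in range(len(planted))]
    mats = simulate_cohort_matrices(cfg, truth, geno)
    samples = list(mats)
    inds = [mats[s].meta["individual"] for s in samples]
    counts = np.stack([local_cis_counts(mats[s]) for s in samples])
    cov = simulate_bin_covariates(n, seed + 1, zero_fraction=0.0)
    z, _ = fire_scores(counts, cov, sample_ids=samples)
    scan = lmm_scan(z, inds, geno, cfg.individuals)
    calls = call_qtls(scan, "FIRE", fdr=fdr)
    called = set(calls["bin"]) if len(calls) else set()
    ps = set(planted.tolist())
    return {"recall": len(called & ps) / len(ps),
            "fdp": len(called - ps) / max(len(called), 1),
            "n_called": len(called), "scan": scan}


def ins_qtl_recovery(seed: int, beta: float = INS_QTL_BETA,
                     n_planted: int = 10, n_null: int = 40,
                     fdr: float = 0.2) -> dict:
    """Plant INS-QTLs at TAD boundaries; phenotype = 200-kb insulation on O/E.

    Null bins are kept >= 11 bins from planted boundaries: the insulation
    window is +/-5 bins and the planted effect another +/-5, so closer bins
    genuinely carry signal.
    """
    rng = np.random.default_rng(seed + 20_000)
    cfg = SimConfig(n_individuals=11, seed=seed, chrom_length=8_000_000)
    truth = default_truth(cfg, batch_shift=0.0)
    n = cfg.n_bins
    bounds = [b for b in truth.tad_boundaries if 8 <= b <= n - 8]
    planted = _pick_separated(rng, bounds, min(n_planted, len(bounds)), min_gap=11)
    pool = [b for b in range(8, n - 8)
            if all(abs(b - p) >= 11 for p in planted)]
    null = _pick_separated(rng, pool, n_null, min_gap=1)
    cand = np.concatenate([planted, null])
    geno = _bin_snps(cfg, cand, rng)
    truth.qtl_effects = [QTLEffect(f"s{k:04d}", "INS", int(planted[k]), beta)
                         for k in range(len(planted))]
    mats = simulate_cohort_matrices(cfg, truth, geno)
    samples = list(mats)
    inds = [mats[s].meta["individual"] for s in samples]
    tracks = np.stack([insulation_score(oe_transform(mats[s]), 200_000)
                       for s in samples])
    scan = lmm_scan(tracks, inds, geno, cfg.individuals)
    calls = call_qtls(scan, "INS", fdr=fdr)
    called = set(calls["bin"]) if len(calls) else set()
    ps = set(planted.tolist())
    return {"recall": len(called & ps) / len(ps),
            "fdp": len(called - ps) / max(len(called), 1),
            "n_called": len(called), "scan": scan}


def contact_qtl_recovery(seed: int, beta: float = CONTACT_QTL_BETA,
                         n_planted: int = 10, n_null: int = 40,
                         fdr: float = 0.2) -> dict:
    """Plant contact-QTLs at matrix cells; phenotype = BNBC-corrected values."""
    rng = np.random.default_rng(seed + 30_000)
    cfg = SimConfig(n_individuals=11, seed=seed, chrom_length=8_000_000)
    truth = default_truth(cfg, batch_shift=0.05)
    n = cfg.n_bins
    cells, used = [], set()
    while len(cells) < n_planted + n_null:
        i = int(rng.integers(5, n - 25))
        d = int(rng.integers(3, 20))
        j = i + d
        if i in used or j in used:
            continue
        used.update([i, j])
        cells.append((i, j))
    planted, _null = cells[:n_planted], cells[n_planted:]
    anchor_bins = sorted({c[0] for c in cells})
    geno = _bin_snps(cfg, np.array(anchor_bins), rng)
    snp_of_bin = {int(r["bin"]): r["snp_id"] for _, r in geno.iterrows()}
    truth.qtl_effects = [QTLEffect(snp_of_bin[i], "CONTACT", (i, j), beta)
                         for i, j in planted]
    mats = simulate_cohort_matrices(cfg, truth, geno)
    samples = list(mats)
    inds = [mats[s].meta["individual"] for s in samples]
    batches = {s: mats[s].meta["batch"] for s in samples}
    corr = bnbc_correct(extract_bands(mats, batches, max_band=30), n,
                        bin_size=cfg.bin_size)
    cell_vals = np.stack([[corr[s].values[i, j] for (i, j) in cells]
                          for s in samples])
    tests, calls = cqtl_scan(cell_vals, cells, inds, geno, cfg.individuals, fdr=fdr)
    called = set() if len(calls) == 0 else {
        (int(r["anchor_i"]), int(r["anchor_j"])) for _, r in calls.iterrows()}
    ps = set(planted)
    return {"recall": len(called & ps) / len(ps),
            "fdp": len(called - ps) / max(len(called), 1),
            "n_called": len(called), "tests": tests}


def lmm_null_rejection(n_sim: int = 1000, seed: int = 0, alpha: float = 0.05,
                       subject_sd: float = 0.5, residual_sd: float = 0.5,
                       n_subjects: int = 11, n_replicates: int = 2) -> float:
    """Type-I error of the replicate-level LMM scan under genotype null."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_subjects), n_replicates)
    N = n_subjects * n_replicates
    rej = 0
    for _ in range(n_sim):
        for _a in range(1000):
            dose = rng.binomial(1, 0.3, n_subjects) + rng.binomial(1, 0.3, n_subjects)
            if np.ptp(dose) > 0:
                break
        y = (rng.normal(0, subject_sd, n_subjects)[groups]
             + rng.normal(0, residual_sd, N))
        X = np.column_stack([np.ones(N), dose[groups].astype(float)])
        fit = fit_random_intercept(y, X, groups)
        if fit.pvalues[1] < alpha:
            rej += 1
    return rej / n_sim


def pc1_tad_recovery(seed: int = 0) -> dict:
    """Compartment and TAD recovery on the default 400-bin chromosome."""
    cfg = SimConfig(n_individuals=2, seed=seed)
    truth = default_truth(cfg, batch_shift=0.0)
    from .synthetic import simulate_genotypes
    geno = simulate_genotypes(cfg, 5)
    mats = simulate_cohort_matrices(cfg, truth, geno)
    m = next(iter(mats.values()))
    oe = oe_transform(m)
    gene_density = (truth.compartment_vector > 0).astype(float) + \
        0.1 * np.random.default_rng(seed).random(cfg.n_bins)
    pc1, diag = compartment_pc1(oe, gene_density)
    if pc1 is None:
        pc1_corr = 0.0
    else:
        ok = np.isfinite(pc1)
        pc1_corr = abs(float(np.corrcoef(pc1[ok], truth.compartment_vector[ok])[0, 1]))
    di = directionality_index(m, 2_000_000)
    tads = call_tads(di, random_state=seed)
    finite = np.flatnonzero(np.isfinite(di))
    in_range = [b for b in truth.tad_boundaries
                if finite.min() + 1 <= b <= finite.max() - 1]
    hits = sum(any(abs(b - f) <= 1 for f in tads.boundaries) for b in in_range)
    return {"pc1_corr": pc1_corr, "pc1_status": diag["status"],
            "tad_recall": hits / max(len(in_range), 1),
            "n_boundaries_called": len(tads.boundaries),
            "n_boundaries_true": len(in_range)}


def synthetic_band_slices(seed: int, shift: float, n_per_batch: int = 4,
                          n_bins: int = 100, n_bands: int = 60):
    """Band slices with cell-specific means and an additive batch-B shift."""
    rng = np.random.default_rng(seed)
    samples = [f"s{k}" for k in range(2 * n_per_batch)]
    batches = ["A"] * n_per_batch + ["B"] * n_per_batch
    slices = []
    for b in range(1, n_bands + 1):
        nc = n_bins - b
        mu = 5.0 - 0.05 * b + rng.normal(0, 0.5, nc)
        x = mu[None, :] + rng.normal(0, 0.3, (2 * n_per_batch, nc))
        x[n_per_batch:] += shift
        slices.append(BandSlice(b, x, batches, samples))
    return slices, samples, batches


def bnbc_batch_eval(seed: int = 0, shift: float = 1.0, n_per_batch: int = 4,
                    n_bins: int = 100, n_bands: int = 60) -> dict:
    """Batch-shift removal and null batch-test uniformity of the BNBC path."""
    n_corrected = n_bands - 8

    def batch_means(corrected, samples, n_a):
        diffs = []
        for b in range(1, n_corrected + 1):
            A = np.stack([np.diagonal(corrected[s].values, b) for s in samples[:n_a]])
            B = np.stack([np.diagonal(corrected[s].values, b) for s in samples[n_a:]])
            diffs.append(B.mean() - A.mean())
        return np.array(diffs)

    sl, samples, _ = synthetic_band_slices(seed, shift, n_per_batch, n_bins, n_bands)
    pre = np.array([s.values[n_per_batch:].mean() - s.values[:n_per_batch].mean()
                    for s in sl[:n_corrected]])
    corr = bnbc_correct(sl, n_bins=n_bins)
    post = batch_means(corr, samples, n_per_batch)

    sl0, samples0, _ = synthetic_band_slices(seed + 1, 0.0, n_per_batch,
                                             n_bins, n_bands)
    corr0 = bnbc_correct(sl0, n_bins=n_bins)
    pv = []
    for b in range(1, n_corrected + 1):
        A = np.stack([np.diagonal(corr0[s].values, b) for s in samples0[:n_per_batch]])
        B = np.stack([np.diagonal(corr0[s].values, b) for s in samples0[n_per_batch:]])
        for c in range(A.shape[1]):
            if A[:, c].std() + B[:, c].std() > 0:
                pv.append(stats.f_oneway(A[:, c], B[:, c]).pvalue)
    pv = np.asarray(pv)
    pv = pv[np.isfinite(pv)]
    ks_p = float(stats.kstest(pv, "uniform").pvalue)
    return {"pre_shift": float(np.mean(np.abs(pre))),
            "post_shift": float(np.mean(np.abs(post))),
            "null_ks_p": ks_p, "n_null_tests": len(pv)}


def permutation_null_calibration(n_runs: int = 50, n_perm: int = 500,
                                 seed: int = 0) -> dict:
    """Uniformity of the permutation machinery under independence.

    Runs :func:`hicpop.variability.correlate_with_tracks` with independent
    external tracks and :func:`hicpop.sharing.bootstrap_null` with QTL sets
    drawn at random from the universe, collecting one p-value per run.
    """
    from .sharing import bootstrap_null, nominal_fraction
    from .variability import VariableRegionSet, correlate_with_tracks

    rng = np.random.default_rng(seed)
    corr_ps, boot_ps = [], []
    n_ind, n_bins_ = 12, 120
    for r in range(n_runs):
        feature = rng.standard_normal((n_ind, n_bins_))
        external = rng.standard_normal((n_ind, n_bins_))
        bins = np.sort(rng.choice(n_bins_, size=15, replace=False))
        regions = VariableRegionSet(regions=[(int(b), int(b)) for b in bins],
                                    metric="DI", fdr=0.1, significant_bins=bins)
        res = correlate_with_tracks(regions, feature, external,
                                    n_perm=n_perm, seed=seed + 1000 + r)
        corr_ps.append(res["p_perm"])

        scan = pd.DataFrame({
            "snp_id": [f"v{k}" for k in range(400)],
            "p": rng.uniform(0, 1, 400),
        })
        qtl = rng.choice(scan["snp_id"], size=40, replace=False)
        obs = nominal_fraction(qtl, scan)["fraction"]
        boot = bootstrap_null(scan["snp_id"], 40, scan, obs,
                              n_perm=n_perm, seed=seed + 2000 + r)
        boot_ps.append(boot["p"])
    corr_ps, boot_ps = np.asarray(corr_ps), np.asarray(boot_ps)
    return {
        "correlation_mean_p": float(corr_ps.mean()),
        "correlation_ks_p": float(stats.kstest(corr_ps, "uniform").pvalue),
        "bootstrap_mean_p": float(boot_ps.mean()),
        "bootstrap_ks_p": float(stats.kstest(boot_ps, "uniform").pvalue),
    }
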