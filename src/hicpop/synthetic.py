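"""Synthetic multi-individual Hi-C cohort with known planted truth.

Emulates a lymphoblastoid-cell-line style design — a handful of individuals,
two Hi-C replicates each, processed in batches — on one synthetic chromosome.
Expected counts combine, multiplicatively on the log scale:

    lambda_ij = depth * (|i-j|+1)^(-decay)
                * exp(c * comp_i * comp_j)            (A/B compartments)
                * tad_factor(i, j)                    (within-domain enrichment)
                * fire_factor(i) * fire_factor(j)     (frequently-interacting bins)
                * loop_factor(i, j)                   (focal loops)
                * qtl_factor(i, j; dosage)            (additive genotype effects)
                * batch_factor(band, batch)           (bandwise distortions)

and observed counts are Poisson(lambda_ij), symmetric.  Replicates of one
individual share every genotype-driven term and differ only by Poisson
sampling and batch.  All randomness flows from the single config seed through
``numpy.random.SeedSequence.spawn`` (one child stream per consumer, in a fixed
documented order: genotypes, truth, matrices, covariates, tracks, reads).

The generative model itself is an artifact choice: no distributional claims
are inherited from real Hi-C beyond the phenomena listed above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactMatrix


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_individuals: int = 11
    n_replicates: int = 2
    chrom_length: int = 16_000_000
    bin_size: int = 40_000
    depth_per_replicate: float = 2_000_000.0
    decay_exponent: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    batch_of_replicate: tuple[str, ...] = ("A", "B")
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        if len(self.batch_of_replicate) < self.n_replicates:
            raise ValueError("every replicate needs a batch label")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    @property
    def individuals(self) -> list[str]:
        return [f"ind{k:02d}" for k in range(self.n_individuals)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            for r in range(self.n_replicates):
                rows.append(
                    {"sample": f"{ind}_rep{r}", "individual": ind, "replicate": r,
                     "batch": self.batch_of_replicate[r]}
                )
        return pd.DataFrame(rows)

    def rng_streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(6)
        names = ["genotypes", "truth", "matrices", "covariates", "tracks", "reads"]
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class QTLEffect:
    """One planted genotype effect: per-dose log factor on a local contact feature."""

    snp_id: str
    phenotype: str  # FIRE | DI | INS | CONTACT | LOOP
    target: object  # bin index, or (i, j) cell
    beta: float  # per alt-dose natural-log factor


@dataclass
class TruthSet:
    """Planted ground truth for one synthetic chromosome."""

    compartment_vector: np.ndarray
    tad_boundaries: list[int]
    fire_bins: dict[int, float]  # bin -> boost factor (> 1)
    loops: list[tuple[int, int, float, str]]  # (i, j, strength, motif orientation)
    qtl_effects: list[QTLEffect] = field(default_factory=list)
    batch_effects: dict[str, np.ndarray] = field(default_factory=dict)  # batch -> per-band log shift
    compartment_coupling: float = 0.3
    tad_strength: float = 1.6

    def validate(self, n_bins: int) -> None:
        if len(self.compartment_vector) != n_bins:
            raise ValueError("compartment vector length mismatch")
        for i, j, s, _ in self.loops:
            if not (0 <= i < j < n_bins):
                raise ValueError("loop anchors must satisfy 0 <= i < j < n_bins")
            if s <= 0:
                raise ValueError("loop strengths must be positive")
        if any(b <= 0 for b in self.fire_bins.values()):
            raise ValueError("FIRE boosts must be positive")


def default_truth(config: SimConfig, rng: np.random.Generator | None = None,
                  tad_spacing: int = 18, fire_fraction: float = 0.05,
                  fire_boost: float = 2.0, n_loops: int = 3,
                  loop_strength: float = 3.0,
                  batch_shift: float = 0.1) -> TruthSet:
    """A realistic default truth: block compartments, regular TADs with jitter,
    a sprinkling of FIRE bins, a few loops, and a mild bandwise batch shift."""
    if rng is None:
        rng = config.rng_streams()["truth"]
    n = config.n_bins
    # compartments: smooth alternating blocks of ~25 bins (1 Mb)
    block = 25
    comp = np.sign(np.sin(2 * np.pi * np.arange(n) / (2 * block) + 0.31))
    comp = comp * (0.7 + 0.3 * rng.random(n))
    # TAD boundaries every ~tad_spacing bins, jittered
    bounds, b = [], tad_spacing
    while b < n - 3:
        bounds.append(int(b))
        b += tad_spacing + int(rng.integers(-3, 4))
    fire = {int(i): fire_boost for i in
            rng.choice(n, size=max(1, int(fire_fraction * n)), replace=False)}
    loops = []
    for _ in range(n_loops):
        i = int(rng.integers(5, n - 30))
        j = i + int(rng.integers(8, 25))
        loops.append((i, j, loop_strength, "+-"))
    batches = sorted(set(config.batch_of_replicate[: config.n_replicates]))
    batch_fx = {bt: np.zeros(n) for bt in batches}
    for k, bt in enumerate(batches[1:], start=1):
        # smooth band-dependent log shift for non-reference batches
        batch_fx[bt] = batch_shift * np.exp(-np.arange(n) / 60.0) * k
    return TruthSet(
        compartment_vector=comp, tad_boundaries=bounds, fire_bins=fire,
        loops=loops, batch_effects=batch_fx,
    )


def simulate_genotypes(config: SimConfig, n_snps: int,
                       mafs: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate a biallelic genotype table (rows = SNPs, dosage columns per individual).

    Each dosage is the sum of two independent allele draws at a frequency
    sampled uniformly from ``config.maf_range`` (or taken from ``mafs``, which
    may include 0 as a degenerate monomorphic case but must stay within
    [0, 0.5]).  Positions are strictly increasing.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = config.rng_streams()["genotypes"]
    if mafs is None:
        lo, hi = config.maf_range
        mafs = rng.uniform(lo, hi, size=n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if len(mafs) != n_snps:
            raise ValueError("mafs length must equal n_snps")
        if (mafs < 0).any() or (mafs > 0.5).any():
            raise ValueError("explicit allele frequencies must lie in [0, 0.5]")
    if n_snps > config.chrom_length:
        raise ValueError("more SNPs than positions")
    pos_set: set[int] = set()
    while len(pos_set) < n_snps:
        draw = rng.integers(1, config.chrom_length + 1, size=2 * n_snps)
        pos_set.update(int(x) for x in draw)
    pool = np.fromiter(pos_set, dtype=int)
    positions = np.sort(rng.choice(pool, size=n_snps, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_snps)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref])
    dosages = rng.binomial(1, mafs[:, None], size=(n_snps, config.n_individuals)) + \
        rng.binomial(1, mafs[:, None], size=(n_snps, config.n_individuals))
    base = pd.DataFrame({
        "snp_id": [f"snp{k:05d}" for k in range(n_snps)],
        "chrom": "chrS",
        "pos": positions.astype(int),
        "ref": ref,
        "alt": alt,
        "maf": mafs,
    })
    dose_df = pd.DataFrame(dosages, columns=config.individuals)
    return pd.concat([base, dose_df], axis=1)


def _log_lambda_base(config: SimConfig, truth: TruthSet) -> np.ndarray:
    n = config.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    log_lam = -config.decay_exponent * np.log(dist + 1.0)
    comp = truth.compartment_vector
    log_lam += truth.compartment_coupling * comp[:, None] * comp[None, :]
    # TAD membership
    domain = np.zeros(n, dtype=int)
    for b in truth.tad_boundaries:
        domain[b:] += 1
    same = (domain[:, None] == domain[None, :]) & (dist > 0)
    log_lam += np.log(truth.tad_strength) * same
    fire_log = np.zeros(n)
    for b, boost in truth.fire_bins.items():
        fire_log[b] = np.log(boost)
    log_lam += fire_log[:, None] + fire_log[None, :]
    for i, j, s, _ in truth.loops:
        log_lam[i, j] += np.log(s)
        log_lam[j, i] += np.log(s)
    return log_lam


# window (in bins) over which planted FIRE / INS / DI QTL effects act; matches
# the 200-kb local window of the QTL-variant phenotypes at 40-kb bins
_QTL_WINDOW = 5


def _apply_qtl(log_lam: np.ndarray, eff: QTLEffect, dose: int) -> None:
    n = log_lam.shape[0]
    shift = eff.beta * dose
    if eff.phenotype == "FIRE":
        b = int(eff.target)
        lo, hi = max(0, b - _QTL_WINDOW), min(n, b + _QTL_WINDOW + 1)
        sel = np.arange(lo, hi)
        sel = sel[sel != b]
        log_lam[b, sel] += shift
        log_lam[sel, b] += shift
    elif eff.phenotype == "INS":
        b = int(eff.target)
        lo, hi = max(0, b - _QTL_WINDOW), min(n, b + _QTL_WINDOW)
        up = np.arange(lo, b)
        down = np.arange(b, hi)
        for i in up:
            log_lam[i, down] += shift
            log_lam[down, i] += shift
    elif eff.phenotype == "DI":
        b = int(eff.target)
        lo = max(0, b - _QTL_WINDOW)
        up = np.arange(lo, b)
        log_lam[b, up] += shift
        log_lam[up, b] += shift
    elif eff.phenotype in ("CONTACT", "LOOP"):
        i, j = eff.target
        log_lam[i, j] += shift
        log_lam[j, i] += shift
    else:
        raise ValueError(f"unknown planted phenotype {eff.phenotype!r}")


def simulate_cohort_matrices(config: SimConfig, truth: TruthSet,
                             genotypes: pd.DataFrame) -> dict[str, ContactMatrix]:
    """Simulate one contact matrix per replicate, keyed by sample id."""
    truth.validate(config.n_bins)
    rng = config.rng_streams()["matrices"]
    n = config.n_bins
    base = _log_lambda_base(config, truth)
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    iu = np.triu_indices(n)
    snp_rows = {eff.snp_id: genotypes.loc[genotypes.snp_id == eff.snp_id]
                for eff in truth.qtl_effects}
    out: dict[str, ContactMatrix] = {}
    for ind in config.individuals:
        log_lam_ind = base.copy()
        for eff in truth.qtl_effects:
            row = snp_rows[eff.snp_id]
            if row.empty:
                raise ValueError(f"planted QTL SNP {eff.snp_id} missing from genotypes")
            dose = int(row.iloc[0][ind])
            if dose >= 0:
                _apply_qtl(log_lam_ind, eff, dose)
        for r in range(config.n_replicates):
            batch = config.batch_of_replicate[r]
            shift = truth.batch_effects.get(batch)
            log_lam = log_lam_ind if shift is None else log_lam_ind + shift[dist]
            lam = np.exp(log_lam)
            lam *= config.depth_per_replicate / lam[iu].sum()
            lam_u = lam[iu]
            if config.overdispersion > 0:
                shape = 1.0 / config.overdispersion
                lam_u = lam_u * rng.gamma(shape, 1.0 / shape, size=lam_u.shape)
            counts_u = rng.poisson(lam_u)
            m = np.zeros((n, n))
            m[iu] = counts_u
            m[(iu[1], iu[0])] = counts_u
            out[f"{ind}_rep{r}"] = ContactMatrix(
                m, config.bin_size, "chrS",
                meta={"individual": ind, "replicate": r, "batch": batch},
            )
    return out


def expected_lambda(config: SimConfig, truth: TruthSet, doses: dict[str, int] | None = None,
                    batch: str | None = None) -> np.ndarray:
    """Analytic expected-count matrix for one replicate (Monte-Carlo oracle hook)."""
    truth.validate(config.n_bins)
    n = config.n_bins
    log_lam = _log_lambda_base(config, truth)
    if doses:
        for eff in truth.qtl_effects:
            if eff.snp_id in doses:
                _apply_qtl(log_lam, eff, doses[eff.snp_id])
    if batch is not None and batch in truth.batch_effects:
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        log_lam = log_lam + truth.batch_effects[batch][dist]
    lam = np.exp(log_lam)
    iu = np.triu_indices(n)
    lam *= config.depth_per_replicate / lam[iu].sum()
    return lam


def simulate_bin_covariates(n_bins: int, seed: int, zero_fraction: float = 0.0):
    """Per-bin effective fragment length, GC and mappability from positive
    distributions; a ``zero_fraction`` of bins gets one covariate zeroed to
    exercise the unreliable-bin filters."""
    from .contact import BinCovariates

    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    eff_len = rng.lognormal(mean=np.log(20_000), sigma=0.25, size=n_bins)
    gc = np.clip(rng.normal(0.45, 0.05, size=n_bins), 0.25, 0.65)
    mapp = rng.uniform(0.7, 1.0, size=n_bins)
    if zero_fraction > 0:
        k = int(round(zero_fraction * n_bins))
        k = min(max(k, 1 if zero_fraction > 0 else 0), n_bins)
        hit = rng.choice(n_bins, size=k, replace=False)
        which = rng.integers(0, 3, size=k)
        eff_len[hit[which == 0]] = 0.0
        gc[hit[which == 1]] = 0.0
        mapp[hit[which == 2]] = 0.0
    return BinCovariates(eff_len, gc, mapp)


def simulate_epigenome_tracks(feature: np.ndarray, target_bins, rho: float,
                              seed: int) -> np.ndarray:
    """Per-individual external tracks correlated with a 3D feature at chosen bins.

    ``feature`` is individuals x bins.  At each target bin the returned track is
    rho * z(feature) + sqrt(1-rho^2) * noise across individuals; elsewhere it is
    independent standard noise.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    feature = np.asarray(feature, dtype=float)
    rng = np.random.default_rng(seed)
    n_ind, n_bins_ = feature.shape
    out = rng.standard_normal((n_ind, n_bins_))
    for b in target_bins:
        col = feature[:, b]
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n_ind)
        out[:, b] = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * out[:, b]
    return out


def simulate_loop_haplotype_reads(loop_ids, het_individuals, imbalance: float,
                                  depth, seed: int,
                                  fixed_total: bool = False) -> pd.DataFrame:
    """Allelic loop-read counts for heterozygous individuals.

    Each (loop, individual) gets a total read count (Poisson with mean ``depth``,
    or exactly ``depth`` when ``fixed_total``) split binomially between the
    strong-allele (S) and weak-allele (W) haplotypes with P(S) = ``imbalance``.
    """
    if not 0.0 <= imbalance <= 1.0:
        raise ValueError("imbalance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=float), (len(loop_ids),))
    rows = []
    for li, loop in enumerate(loop_ids):
        for ind in het_individuals:
            total = int(depth_arr[li]) if fixed_total else int(rng.poisson(depth_arr[li]))
            s = int(rng.binomial(total, imbalance)) if total > 0 else 0
            rows.append({"loop": loop, "individual": ind,
                         "s_count": s, "w_count": total - s})
    return pd.DataFrame(rows)
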