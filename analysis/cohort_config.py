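"""Shared cohort construction for the numbered analysis scripts.

One 16-Mb synthetic chromosome (400 x 40-kb bins), 16 individuals (11
discovery + 5 held-out), 2 replicates each in two batches, with planted
FIRE-, INS- and contact-QTL effects of ~1.5 phenotype SD per allele dose.
"""

from __future__ import annotations

import numpy as np

COHORT_SEED = 20_240_401

N_DISCOVERY = 11
N_HELDOUT = 5


def build_cohort(seed: int = COHORT_SEED) -> dict:
    from hicpop import (QTLEffect, SimConfig, default_truth,
                        simulate_bin_covariates, simulate_cohort_matrices)
    from hicpop.evaluation import (_bin_snps, _pick_separated,
                                   CONTACT_QTL_BETA, FIRE_QTL_BETA,
                                   INS_QTL_BETA)

    cfg = SimConfig(n_individuals=N_DISCOVERY + N_HELDOUT, seed=seed)
    rng = np.random.default_rng(seed + 1)
    truth = default_truth(cfg, batch_shift=0.1)
    n = cfg.n_bins

    fire_targets = _pick_separated(rng, np.arange(10, n - 10), 15, min_gap=6)
    ins_pool = [b for b in truth.tad_boundaries if 8 <= b <= n - 8
                and all(abs(b - f) >= 6 for f in fire_targets)]
    ins_targets = _pick_separated(rng, ins_pool, 8, min_gap=11)
    used = set(fire_targets) | set(ins_targets)
    contact_cells = []
    while len(contact_cells) < 8:
        i = int(rng.integers(5, n - 30))
        j = i + int(rng.integers(3, 20))
        if i in used or j in used:
            continue
        used.update([i, j])
        contact_cells.append((i, j))

    null_pool = [b for b in range(10, n - 10)
                 if all(abs(b - u) >= 6 for u in used)]
    null_bins = _pick_separated(rng, null_pool, 80, min_gap=2)

    snp_bins = np.concatenate([fire_targets, ins_targets,
                               [c[0] for c in contact_cells], null_bins])
    geno = _bin_snps(cfg, snp_bins, rng)
    snp_of_bin = {int(r["bin"]): r["snp_id"] for _, r in geno.iterrows()}

    truth.qtl_effects = (
        [QTLEffect(snp_of_bin[int(b)], "FIRE", int(b), FIRE_QTL_BETA)
         for b in fire_targets]
        + [QTLEffect(snp_of_bin[int(b)], "INS", int(b), INS_QTL_BETA)
           for b in ins_targets]
        + [QTLEffect(snp_of_bin[i], "CONTACT", (i, j), CONTACT_QTL_BETA)
           for i, j in contact_cells]
    )
    mats = simulate_cohort_matrices(cfg, truth, geno)
    cov = simulate_bin_covariates(n, seed + 2, zero_fraction=0.02)
    individuals = cfg.individuals
    return {
        "config": cfg,
        "truth": truth,
        "genotypes": geno,
        "matrices": mats,
        "covariates": cov,
        "discovery_ids": individuals[:N_DISCOVERY],
        "heldout_ids": individuals[N_DISCOVERY:],
        "fire_targets": fire_targets,
        "ins_targets": ins_targets,
        "contact_cells": contact_cells,
    }
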