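#!/usr/bin/env python
"""CTCF motif disruption and loop strength on the synthetic cohort.

Key positions of the CTCF PWM, strong/weak allele classification of SNPs in
synthetic convergent-motif loop anchors, genotype regression of normalized
loop strengths, and the haplotype allelic-imbalance test.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from cohort_config import build_cohort, COHORT_SEED  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from hicpop import quantile_normalize, simulate_loop_haplotype_reads
    from hicpop.motifs import (MA0139_PFM, PWM, allelic_imbalance,
                               classify_motif_snps, key_positions,
                               loop_genotype_regression, s_allele_dose)

    pwm = PWM.from_jaspar(MA0139_PFM)
    keys = key_positions(pwm, threshold=0.75)
    print(f"CTCF PWM {pwm.name}: consensus {pwm.consensus}, "
          f"{len(keys)} key positions (0-based columns {keys})")

    cohort = build_cohort(seed=COHORT_SEED)
    cfg, truth, geno, mats = (cohort[k] for k in
                              ("config", "truth", "genotypes", "matrices"))
    rng = np.random.default_rng(COHORT_SEED + 5)

    # place a convergent CTCF motif pair at each planted loop's anchors and a
    # motif-disrupting SNP at a key column of the left-anchor motif
    motif_rows, snp_rows = [], []
    for k, (i, j, strength, _orient) in enumerate(truth.loops):
        left_start = i * cfg.bin_size + 200
        right_start = j * cfg.bin_size + 200
        motif_rows.append({"motif_id": f"L{k}_left", "start": left_start,
                           "end": left_start + pwm.length - 1, "strand": "+"})
        motif_rows.append({"motif_id": f"L{k}_right", "start": right_start,
                           "end": right_start + pwm.length - 1, "strand": "-"})
        col = keys[int(rng.integers(len(keys)))]
        cons = pwm.consensus[col]
        weak = rng.choice([b for b in "ACGT" if b != cons])
        snp_rows.append({"snp_id": f"motif_snp{k}", "pos": left_start + col,
                         "ref": cons, "alt": weak})
    motifs = pd.DataFrame(motif_rows)
    msnps = pd.DataFrame(snp_rows)
    calls = classify_motif_snps(msnps, motifs, pwm)
    print(f"{len(calls)}/{len(msnps)} anchor SNPs are motif-disrupting "
          "(strong/weak alleles assigned)")

    # genotypes for the motif SNPs and S-dose-dependent loop strengths
    inds = cfg.individuals
    samples = list(mats)
    qn_mats = dict(zip(samples, quantile_normalize([mats[s] for s in samples])))
    strength_rows = []
    geno_rows = []
    for k, (i, j, *_rest) in enumerate(truth.loops):
        dos = rng.binomial(1, 0.45, len(inds)) + rng.binomial(1, 0.45, len(inds))
        rec = {"snp_id": f"motif_snp{k}", "ref": msnps.iloc[k]["ref"],
               "alt": msnps.iloc[k]["alt"]}
        rec.update(dict(zip(inds, (int(d) for d in dos))))
        geno_rows.append(rec)
        row = {"snp_id": f"motif_snp{k}"}
        call = calls[calls["snp_id"] == f"motif_snp{k}"].iloc[0]
        for ind_idx, ind in enumerate(inds):
            reps = [qn_mats[s].values[i, j] for s in samples
                    if s.startswith(ind)]
            base = float(np.mean(reps))
            s_dose = s_allele_dose(call, int(dos[ind_idx]))
            row[ind] = base * (1.0 + 0.25 * s_dose)  # planted S-allele boost
        strength_rows.append(row)
    mgeno = pd.DataFrame(geno_rows)
    strengths = pd.DataFrame(strength_rows,
                             index=[f"L{k}" for k in range(len(truth.loops))])
    reg = loop_genotype_regression(strengths, calls, mgeno, inds)
    print(f"loop strength ~ S dose: slope {reg['slope']:.3f} per S allele, "
          f"p {reg['p']:.2e} ({reg['excluded']} loops without heterozygotes "
          "excluded)")
    reg["table"].to_csv(ROOT / "results" / "loop_genotype_strengths.tsv",
                        sep="\t", index=False)

    # allelic imbalance in S/W heterozygotes (planted imbalance 0.65)
    het_inds = [ind for ind in inds
                if any(int(r[ind]) == 1 for _, r in mgeno.iterrows())]
    reads = simulate_loop_haplotype_reads(
        [f"L{k}" for k in range(len(truth.loops))], het_inds,
        imbalance=0.65, depth=30, seed=COHORT_SEED + 6)
    ai = allelic_imbalance(reads, min_total=10)
    print(f"allelic imbalance: mean S fraction "
          f"{np.mean(ai['fractions']):.3f} over {ai['n_points']} points "
          f"({ai['n_filtered']} filtered at <10 reads), one-sided t p "
          f"{ai['p']:.2e}")


if __name__ == "__main__":
    main()
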