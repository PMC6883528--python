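#!/usr/bin/env python
"""Simulate the synthetic Hi-C cohort every later step consumes.

11 discovery + 5 held-out individuals, 2 replicates each, one 16-Mb
chromosome at 40-kb resolution, with planted compartments, TADs, FIRE bins,
loops, FIRE/INS/contact QTL effects and a bandwise batch shift.  Full
matrices go to scratch/cohort/ (regenerable); small summaries and the truth
to results/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from cohort_config import build_cohort, COHORT_SEED  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from hicpop import io

    cohort = build_cohort(seed=COHORT_SEED)
    cfg, truth, geno, mats, cov = (cohort[k] for k in
                                   ("config", "truth", "genotypes",
                                    "matrices", "covariates"))

    outdir = ROOT / "scratch" / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, m in mats.items():
        io.write_triplets(m, outdir / f"{sample}.triplets.tsv")
    geno.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    io.write_covariates(cov, outdir / "covariates.tsv")

    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)
    cfg.sample_sheet().assign(
        split=lambda df: np.where(
            df["individual"].isin(cohort["discovery_ids"]), "discovery",
            "validation")
    ).to_csv(resdir / "sample_sheet.tsv", sep="\t", index=False)
    io.write_truth(truth, resdir / "truth.json")

    depths = {s: int(m.values[np.triu_indices(m.n_bins)].sum())
              for s, m in mats.items()}
    summary = {
        "n_individuals": cfg.n_individuals,
        "n_replicates": cfg.n_replicates,
        "n_bins": cfg.n_bins,
        "bin_size": cfg.bin_size,
        "median_depth": int(np.median(list(depths.values()))),
        "n_snps": len(geno),
        "planted": {
            "tad_boundaries": len(truth.tad_boundaries),
            "fire_bins": len(truth.fire_bins),
            "loops": len(truth.loops),
            "qtl_effects": len(truth.qtl_effects),
        },
    }
    (resdir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"simulated {len(mats)} replicate matrices "
          f"({cfg.n_bins} bins, median depth {summary['median_depth']:,} pairs)")
    print(f"planted: {summary['planted']}")
    print(f"matrices in {outdir}, summaries in {resdir}")


if __name__ == "__main__":
    main()
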