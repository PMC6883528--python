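"""CTCF motif disruption and loop strength.

A JASPAR-style position weight matrix defines "key" columns where one base
carries more than 0.75 probability.  A SNP falling on a key column of a motif
occurrence, with exactly one allele matching the consensus base
(strand-adjusted), splits its alleles into strong (S, consensus-matching) and
weak (W).  Loop interaction strength is then regressed on S-allele dose
(strengths normalized so each SNP's heterozygote class means 1), and phased
loop-read counts give a direct allelic-imbalance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: packaged JASPAR MA0139.1 (CTCF) count matrix
MA0139_PFM = Path(__file__).parent / "data" / "MA0139.1.pfm"


@dataclass
class PWM:
    """4 x L base-probability matrix (rows A, C, G, T)."""

    probs: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM must be 4 x L")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[k] for k in np.argmax(self.probs, axis=0))

    @classmethod
    def from_jaspar(cls, path, pseudocount: float = 0.0) -> "PWM":
        """Parse a JASPAR .pfm text file (bracketed or bare count rows)."""
        name = ""
        rows: dict[str, list[float]] = {}
        order = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    continue
                parts = line.replace("[", " ").replace("]", " ").split()
                if parts[0].upper() in BASES:
                    base = parts[0].upper()
                    vals = [float(v) for v in parts[1:]]
                else:
                    base = BASES[len(order)]
                    vals = [float(v) for v in parts]
                rows[base] = vals
                order.append(base)
        counts = np.array([rows[b] for b in BASES]) + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        return cls(probs, name=name)


def key_positions(pwm: PWM, threshold: float = 0.75) -> list[int]:
    """0-based PWM columns whose maximum base probability strictly exceeds threshold."""
    return [int(c) for c in np.flatnonzero(pwm.probs.max(axis=0) > threshold)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def classify_motif_snps(snps: pd.DataFrame, motifs: pd.DataFrame, pwm: PWM,
                        threshold: float = 0.75) -> pd.DataFrame:
    """Classify SNPs inside motif occurrences into strong/weak allele calls.

    ``snps`` needs snp_id, pos, ref, alt (forward-strand alleles); ``motifs``
    needs motif_id, start, end (1-based inclusive, end - start + 1 == PWM
    length) and strand.  A call is emitted only when the hit column is a key
    position and exactly one strand-adjusted allele equals the consensus base.
    S/W alleles are reported on the forward genome strand.
    """
    keys = set(key_positions(pwm, threshold))
    consensus = pwm.consensus
    rows = []
    for _, m in motifs.iterrows():
        if int(m["end"]) - int(m["start"]) + 1 != pwm.length:
            raise ValueError(f"motif {m.get('motif_id')} length != PWM length")
        hit = snps[(snps["pos"] >= m["start"]) & (snps["pos"] <= m["end"])]
        for _, s in hit.iterrows():
            col = (int(s["pos"]) - int(m["start"]) if m["strand"] == "+"
                   else int(m["end"]) - int(s["pos"]))
            if col not in keys:
                continue
            cons = consensus[col]
            alleles = {str(s["ref"]).upper(), str(s["alt"]).upper()}
            if m["strand"] == "-":
                motif_alleles = {a.translate(_COMP) for a in alleles}
            else:
                motif_alleles = alleles
            matching = [a for a in motif_alleles if a == cons]
            if len(matching) != 1:
                continue
            strong_motif = matching[0]
            strong = (strong_motif.translate(_COMP) if m["strand"] == "-"
                      else strong_motif)
            weak = (alleles - {strong}).pop()
            rows.append({"snp_id": s["snp_id"], "motif_id": m["motif_id"],
                         "column": col, "strand": m["strand"],
                         "strong_allele": strong, "weak_allele": weak,
                         "ref": s["ref"], "alt": s["alt"]})
    return pd.DataFrame(rows)


def s_allele_dose(call: pd.Series, dosage_alt: int) -> int:
    """Convert an alt-allele dosage into an S-allele dose for one motif-SNP call."""
    if dosage_alt < 0:
        return -1
    return dosage_alt if call["strong_allele"] == call["alt"] else 2 - dosage_alt


def loop_genotype_regression(strengths: pd.DataFrame, calls: pd.DataFrame,
                             genotypes: pd.DataFrame,
                             individual_ids: list[str]) -> dict:
    """Pooled regression of normalized loop strength on S-allele dose.

    ``strengths`` is loops x individuals (index = loop id, one ``snp_id``
    column naming the motif-disrupting SNP of the loop's anchor).  Per loop:
    individuals are classed WW/WS/SS by S dose and strengths are divided by the
    heterozygote-class mean (loops without heterozygotes are excluded and
    counted).  Returns the pooled slope per S allele, its p, and the long table.
    """
    geno = genotypes.set_index("snp_id")
    call_by_snp = calls.set_index("snp_id")
    rows = []
    excluded = 0
    for loop_id, loop in strengths.iterrows():
        snp_id = loop["snp_id"]
        call = call_by_snp.loc[snp_id]
        snp = geno.loc[snp_id]
        doses, vals = [], []
        for ind in individual_ids:
            d = s_allele_dose(call, int(snp[ind]))
            v = loop[ind]
            if d < 0 or not np.isfinite(v):
                continue
            doses.append(d)
            vals.append(float(v))
        doses = np.array(doses)
        vals = np.array(vals)
        het = vals[doses == 1]
        if len(het) == 0 or het.mean() == 0:
            excluded += 1
            continue
        norm = vals / het.mean()
        for d, v in zip(doses, norm):
            rows.append({"loop": loop_id, "snp_id": snp_id,
                         "s_dose": int(d), "normalized": v})
    table = pd.DataFrame(rows)
    if table.empty or table["s_dose"].nunique() < 2:
        return {"slope": np.nan, "p": np.nan, "table": table, "excluded": excluded}
    fit = stats.linregress(table["s_dose"], table["normalized"])
    return {"slope": float(fit.slope), "p": float(fit.pvalue), "table": table,
            "excluded": excluded}


def allelic_imbalance(counts: pd.DataFrame, min_total: int = 10) -> dict:
    """One-sided allelic-imbalance test on phased loop reads.

    Keeps (loop, individual) points with s_count + w_count >= ``min_total``,
    computes the S-haplotype fraction per point, and tests mean fraction > 0.5
    with a one-sample one-sided t-test.  Returns NaNs when every point is
    filtered.
    """
    total = counts["s_count"] + counts["w_count"]
    kept = counts[total >= min_total].copy()
    n_filtered = len(counts) - len(kept)
    if kept.empty:
        return {"fractions": np.array([]), "t": np.nan, "p": np.nan,
                "n_points": 0, "n_filtered": n_filtered}
    frac = (kept["s_count"] / (kept["s_count"] + kept["w_count"])).to_numpy()
    if len(frac) < 2 or np.ptp(frac) == 0:
        p = 0.5 if np.allclose(frac, 0.5) else np.nan
        return {"fractions": frac, "t": 0.0 if np.allclose(frac, 0.5) else np.nan,
                "p": p, "n_points": len(frac), "n_filtered": n_filtered}
    res = stats.ttest_1samp(frac, 0.5, alternative="greater")
    return {"fractions": frac, "t": float(res.statistic), "p": float(res.pvalue),
            "n_points": len(frac), "n_filtered": n_filtered}
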