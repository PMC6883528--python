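"""Plain-text readers and writers: sparse triplet matrices, tracks, tables.

Internal coordinates are 0-based half-open bins; BED output follows the BED
convention (0-based half-open), bedGraph likewise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import ContactMatrix


def write_triplets(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (i <= j) as bin_i<TAB>bin_j<TAB>value."""
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.values[iu]
    keep = np.isfinite(vals) & (vals != 0)
    df = pd.DataFrame({"bin_i": iu[0][keep], "bin_j": iu[1][keep],
                       "count": vals[keep]})
    df.to_csv(path, sep="\t", index=False, header=False)


def read_triplets(path, n_bins: int, bin_size: int, chrom: str = "chr1") -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["bin_i", "bin_j", "count"])
    m = np.zeros((n_bins, n_bins))
    i = df["bin_i"].to_numpy(dtype=int)
    j = df["bin_j"].to_numpy(dtype=int)
    v = df["count"].to_numpy(dtype=float)
    m[i, j] = v
    m[j, i] = v
    return ContactMatrix(m, bin_size, chrom)


def write_covariates(cov, path) -> None:
    pd.DataFrame({"bin": np.arange(cov.n_bins), "eff_len": cov.eff_len,
                  "gc": cov.gc, "mappability": cov.mappability}).to_csv(
        path, sep="\t", index=False)


def read_covariates(path):
    from .contact import BinCovariates

    df = pd.read_csv(path, sep="\t")
    return BinCovariates(df["eff_len"].to_numpy(), df["gc"].to_numpy(),
                         df["mappability"].to_numpy())


def write_bedgraph(track: np.ndarray, bin_size: int, chrom: str, path) -> None:
    rows = []
    for b, v in enumerate(np.asarray(track, dtype=float)):
        if np.isfinite(v):
            rows.append((chrom, b * bin_size, (b + 1) * bin_size, v))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_bed_regions(regions, bin_size: int, chrom: str, path) -> None:
    """Write (start_bin, end_bin) inclusive bin intervals as BED lines."""
    rows = [(chrom, lo * bin_size, (hi + 1) * bin_size) for lo, hi in regions]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_truth(truth, path) -> None:
    payload = {
        "note": "synthetic planted truth; all distributions are artifact choices",
        "compartment_vector": np.asarray(truth.compartment_vector).tolist(),
        "tad_boundaries": list(map(int, truth.tad_boundaries)),
        "fire_bins": {str(k): float(v) for k, v in truth.fire_bins.items()},
        "loops": [[int(i), int(j), float(s), o] for i, j, s, o in truth.loops],
        "qtl_effects": [
            {"snp_id": e.snp_id, "phenotype": e.phenotype,
             "target": e.target if np.isscalar(e.target) else list(e.target),
             "beta": float(e.beta)}
            for e in truth.qtl_effects],
        "batch_effects": {k: np.asarray(v).tolist()
                          for k, v in truth.batch_effects.items()},
    }
    Path(path).write_text(json.dumps(payload))
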