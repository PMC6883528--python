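"""Reference-genome bookkeeping: hg19 autosome lengths and fixed-width binning."""

from __future__ import annotations

import math

#: hg19 autosome lengths in bp (chr1..chr22).
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
}

#: MHC locus excluded from testable bins (hg19 coordinates, 1-based inclusive).
MHC_REGION = ("chr6", 28477797, 33448354)


def n_bins(chrom_length: int, bin_size: int) -> int:
    """Number of fixed-width bins tiling a chromosome; the last partial bin is kept."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    return math.ceil(chrom_length / bin_size)


def total_bins(lengths: dict[str, int], bin_size: int) -> int:
    """Total bin count over a set of chromosomes (ceiling per chromosome)."""
    return sum(n_bins(length, bin_size) for length in lengths.values())


def bin_of_position(pos: int, bin_size: int) -> int:
    """0-based bin index of a 1-based genomic position."""
    if pos < 1:
        raise ValueError(f"position {pos} is not 1-based")
    return (pos - 1) // bin_size
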