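"""Contact-matrix processing.

Turns binned intra-chromosomal read-pair counts into the normalized matrices all
downstream phenotypes consume:

* :func:`bin_read_pairs` — tally read pairs into a symmetric binned count matrix;
* :func:`hicnorm` — Poisson log-linear bias correction against effective fragment
  length and GC content, with mappability as an offset;
* :func:`quantile_normalize` — cross-sample quantile normalization (reference =
  mean of order statistics);
* :func:`oe_transform` — observed/expected by mean contact frequency per distance.

Bins are 0-based half-open internally: bin ``k`` covers ``[k*bin_size, (k+1)*bin_size)``.
Unmappable bins (any covariate equal to zero) are carried as NA rows/columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .genome import n_bins as _n_bins


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal matrix for one chromosome of one sample.

    ``values`` holds raw counts or normalized values; ``mask`` flags NA bins whose
    rows/columns are NaN throughout.
    """

    values: np.ndarray
    bin_size: int
    chrom: str = "chr1"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.values.copy(), self.bin_size, self.chrom, self.mask.copy(), dict(self.meta)
        )


@dataclass
class BinCovariates:
    """Per-bin HiCNorm covariates: effective fragment length, GC content, mappability."""

    eff_len: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray

    def __post_init__(self) -> None:
        self.eff_len = np.asarray(self.eff_len, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        self.mappability = np.asarray(self.mappability, dtype=float)
        n = len(self.eff_len)
        if len(self.gc) != n or len(self.mappability) != n:
            raise ValueError("covariate vectors must have equal length")
        if (self.eff_len < 0).any() or (self.gc < 0).any() or (self.mappability < 0).any():
            raise ValueError("covariates must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.eff_len)

    @property
    def unreliable(self) -> np.ndarray:
        """Bins with any covariate equal to zero (assigned NA downstream)."""
        return (self.eff_len == 0) | (self.gc == 0) | (self.mappability == 0)


def bin_read_pairs(
    pairs, chrom_length: int, bin_size: int, chrom: str = "chr1"
) -> ContactMatrix:
    """Tally intra-chromosomal read pairs into a symmetric binned count matrix.

    Positions are 1-based 5' coordinates; bin index = floor((pos-1)/bin_size).
    Each pair contributes one count to its (i, j) cell (stored symmetrically).
    """
    n = _n_bins(chrom_length, bin_size)
    m = np.zeros((n, n), dtype=float)
    for pos_a, pos_b in pairs:
        if not (1 <= pos_a <= chrom_length and 1 <= pos_b <= chrom_length):
            raise ValueError(f"position pair ({pos_a}, {pos_b}) outside [1, {chrom_length}]")
        i = (pos_a - 1) // bin_size
        j = (pos_b - 1) // bin_size
        m[i, j] += 1
        if i != j:
            m[j, i] += 1
    return ContactMatrix(m, bin_size, chrom)


def _apply_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = values.copy()
    out[mask, :] = np.nan
    out[:, mask] = np.nan
    return out


def hicnorm(matrix: ContactMatrix, cov: BinCovariates) -> ContactMatrix:
    """HiCNorm-style bias correction of a raw count matrix.

    Fits a Poisson log-linear regression of upper-triangle counts on
    log(effLen_i * effLen_j) and log(GC_i * GC_j) with offset
    log(map_i * map_j), per chromosome, and returns observed/fitted values.
    Bins with any zero covariate become NA rows/columns.  On GLM failure the
    raw matrix is returned with ``meta['hicnorm_status'] == 'failed'``.
    """
    if cov.n_bins != matrix.n_bins:
        raise ValueError("covariates and matrix disagree on bin count")
    vals = matrix.values
    finite = np.isfinite(vals)
    if not np.allclose(vals[finite], np.round(vals[finite])):
        raise ValueError("hicnorm expects raw integer counts")

    bad = cov.unreliable | matrix.mask
    good = np.flatnonzero(~bad)
    if len(good) < 3:
        out = matrix.copy()
        out.mask = bad
        out.values = _apply_mask(out.values, bad)
        out.meta["hicnorm_status"] = "failed"
        warnings.warn("hicnorm: too few reliable bins; returning raw counts")
        return out

    gi, gj = np.meshgrid(good, good, indexing="ij")
    upper = gi < gj
    ii, jj = gi[upper], gj[upper]
    y = vals[ii, jj]
    x_len = np.log(cov.eff_len[ii] * cov.eff_len[jj])
    x_gc = np.log(cov.gc[ii] * cov.gc[jj])
    offset = np.log(cov.mappability[ii] * cov.mappability[jj])
    X = np.column_stack([np.ones_like(x_len), x_len, x_gc])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        if not np.all(np.isfinite(fit.params)):
            raise RuntimeError("non-finite GLM coefficients")
    except Exception:
        out = matrix.copy()
        out.mask = bad
        out.values = _apply_mask(out.values, bad)
        out.meta["hicnorm_status"] = "failed"
        warnings.warn("hicnorm: Poisson GLM did not converge; returning raw counts")
        return out

    # fitted values for every good (i, j) pair, diagonal included
    b0, b_len, b_gc = fit.params
    log_len = np.log(cov.eff_len[good])
    log_gc = np.log(cov.gc[good])
    log_map = np.log(cov.mappability[good])
    eta = (
        b0
        + b_len * (log_len[:, None] + log_len[None, :])
        + b_gc * (log_gc[:, None] + log_gc[None, :])
        + (log_map[:, None] + log_map[None, :])
    )
    fitted = np.exp(eta)

    out_vals = np.full_like(vals, np.nan)
    out_vals[np.ix_(good, good)] = vals[np.ix_(good, good)] / fitted
    out = ContactMatrix(out_vals, matrix.bin_size, matrix.chrom, mask=bad)
    out.meta["hicnorm_status"] = "ok"
    out.meta["hicnorm_params"] = fit.params.copy()
    return out


def _qn_rows(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows (samples) of a 2-D array; NaN entries preserved.

    Reference distribution = mean of per-sample order statistics, interpolated on
    a common quantile grid when samples differ in non-NA counts.  Tied values
    receive the average of the tied reference values (average ranks).
    """
    from scipy.stats import rankdata

    n_samples, _ = x.shape
    counts = np.sum(np.isfinite(x), axis=1)
    grid_n = int(counts.max())
    if grid_n == 0:
        return x.copy()
    qgrid = np.linspace(0.0, 1.0, grid_n)
    ref = np.zeros(grid_n)
    for s in range(n_samples):
        v = np.sort(x[s][np.isfinite(x[s])])
        if len(v) == 0:
            ref += 0.0
            continue
        if len(v) == 1:
            ref += v[0]
        else:
            ref += np.interp(qgrid, np.linspace(0.0, 1.0, len(v)), v)
    ref /= n_samples

    out = np.full_like(x, np.nan)
    for s in range(n_samples):
        idx = np.flatnonzero(np.isfinite(x[s]))
        if len(idx) == 0:
            continue
        ranks = rankdata(x[s, idx], method="average")
        denom = max(len(idx) - 1, 1)
        out[s, idx] = np.interp((ranks - 1) / denom, qgrid, ref)
    return out


def quantile_normalize(samples):
    """Quantile-normalize a set of equal-shape tracks or contact matrices.

    Accepts a list of 1-D arrays, 2-D arrays, or :class:`ContactMatrix` objects
    (matrices are normalized on their upper triangle and re-symmetrized).  With
    fewer than two samples the inputs are returned unchanged with a warning.
    """
    items = list(samples)
    if len(items) < 2:
        warnings.warn("quantile_normalize: fewer than 2 samples; no-op")
        return [it.copy() if hasattr(it, "copy") else it for it in items]

    is_cm = isinstance(items[0], ContactMatrix)
    if is_cm:
        n = items[0].n_bins
        iu = np.triu_indices(n)
        flat = np.stack([it.values[iu] for it in items])
    else:
        arrs = [np.asarray(it, dtype=float) for it in items]
        shape = arrs[0].shape
        if any(a.shape != shape for a in arrs):
            raise ValueError("all samples must share one shape")
        flat = np.stack([a.ravel() for a in arrs])

    norm = _qn_rows(flat)

    if is_cm:
        out = []
        for k, it in enumerate(items):
            m = np.full((n, n), np.nan)
            m[iu] = norm[k]
            m[(iu[1], iu[0])] = norm[k]
            cm = ContactMatrix(m, it.bin_size, it.chrom, mask=it.mask.copy(), meta=dict(it.meta))
            out.append(cm)
        return out
    return [norm[k].reshape(shape) for k in range(len(items))]


def oe_transform(matrix: ContactMatrix) -> ContactMatrix:
    """Observed/expected transform.

    Expected value at distance d = mean of non-NA entries on diagonal offset d of
    the same matrix; distances with zero expected value become NA.
    """
    n = matrix.n_bins
    vals = matrix.values
    out = np.full_like(vals, np.nan)
    expected = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(vals, offset=d)
        finite = np.isfinite(diag)
        if finite.any():
            e = diag[finite].mean()
            expected[d] = e
            if e > 0:
                idx = np.arange(n - d)
                out[idx, idx + d] = diag / e
                out[idx + d, idx] = diag / e
    res = ContactMatrix(out, matrix.bin_size, matrix.chrom, mask=matrix.mask.copy())
    res.meta["expected_by_distance"] = expected
    return res
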