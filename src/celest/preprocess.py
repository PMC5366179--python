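"""RMA-style preprocessing: background correction, quantile normalisation,
median-polish summarisation.

The background model is the normal + exponential convolution: observed
intensity X = S + B with signal S ~ Exp(theta) and background noise
B ~ N(mu, sigma^2), estimated per array by the method of moments and
inverted to the posterior expected signal E[S | X].  Frozen reference
parameter vectors are not used; everything is estimated from the cohort
at hand, so the pipeline can equally start from an already-summarised
matrix and skip this module.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.stats import norm

from .core_io import ExpressionMatrix
from .simulate import probe_gene_groups

logger = logging.getLogger("celest")


# ---------------------------------------------------------------------------
# Background correction (normal + exponential convolution)
# ---------------------------------------------------------------------------


def _normexp_moments(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments estimate of (mu, sigma, theta) for X = N(mu, s^2) + Exp(theta).

    Moments: E X = mu + theta, Var X = sigma^2 + theta^2,
    third central moment = 2 theta^3 (the normal part is symmetric).
    """
    m1 = float(np.mean(x))
    m2 = float(np.var(x))
    m3 = float(np.mean((x - m1) ** 3))
    theta = (max(m3, 0.0) / 2.0) ** (1.0 / 3.0)
    theta = max(theta, 1e-6 * max(m1, 1.0))
    sigma2 = m2 - theta**2
    sigma = np.sqrt(max(sigma2, 1e-6 * m2 if m2 > 0 else 1e-12))
    mu = m1 - theta
    return mu, sigma, theta


def background_correct(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Per-array normexp background correction on linear-scale intensities.

    Returns the posterior expected signal, strictly positive and monotone
    non-decreasing in the input within each array.
    """
    x = raw.values
    if np.any(x <= 0):
        raise ValueError("background correction requires strictly positive intensities")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0.0:
            # degenerate array: no moment information, return tiny constant signal
            out[:, j] = np.full_like(col, 1e-6 * max(col[0], 1.0))
            continue
        mu, sigma, theta = _normexp_moments(col)
        a = col - mu - sigma**2 / theta
        # E[S|X] = a + sigma * phi(a/sigma) / Phi(a/sigma), computed stably in logs
        z = a / sigma
        log_ratio = norm.logpdf(z) - norm.logcdf(z)
        out[:, j] = a + sigma * np.exp(log_ratio)
    if np.any(out <= 0):  # numerically clipped tail
        out = np.maximum(out, np.finfo(float).tiny)
    return ExpressionMatrix(out, list(raw.gene_ids), list(raw.sample_ids))


# ---------------------------------------------------------------------------
# Quantile normalisation
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to the across-column mean of order statistics.

    Within-column ranks are preserved; ties receive the mean of the tied
    reference values, which makes the operation idempotent.
    """
    x = matrix.values
    if x.shape[1] < 2:
        warnings.warn("quantile normalisation needs >=2 samples; returning input unchanged")
        return ExpressionMatrix(x.copy(), list(matrix.gene_ids), list(matrix.sample_ids))
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        assigned = np.empty_like(col)
        assigned[order[:, j]] = reference
        # average the reference values over tied input positions
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return ExpressionMatrix(out, list(matrix.gene_ids), list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# Median polish summarisation
# ---------------------------------------------------------------------------


def _low_median(v: np.ndarray) -> float:
    """Lower median: for even length, the lower of the two middle values."""
    v = np.sort(v)
    return float(v[(len(v) - 1) // 2])


def median_polish(
    table: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D table.

    Alternates row- and column-median sweeps (lower-median convention for
    ties) until the largest absolute adjustment falls below ``tol`` or
    ``max_iter`` sweeps.  Returns (overall, row_effects, col_effects,
    residuals) with overall + row + col + residual == table exactly.
    """
    z = np.asarray(table, dtype=float).copy()
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median polish needs a non-empty 2-D table")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        delta = 0.0
        rmed = np.sort(z, axis=1)[:, (nc - 1) // 2]
        z -= rmed[:, None]
        row += rmed
        delta = max(delta, float(np.max(np.abs(rmed))) if nr else 0.0)
        cmed_of_row = _low_median(row)
        row -= cmed_of_row
        overall += cmed_of_row
        cmed = np.sort(z, axis=0)[(nr - 1) // 2, :]
        z -= cmed[None, :]
        col += cmed
        delta = max(delta, float(np.max(np.abs(cmed))) if nc else 0.0)
        rmed_of_col = _low_median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        if delta < tol:
            break
    return overall, row, col, z


def summarize_median_polish(probe_matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Summarise a log2-scale probe-level matrix to one value per gene.

    Probe rows are grouped by gene id (``<gene>::p<i>`` labels); for each
    gene the probe x sample submatrix is median-polished and the summary is
    overall effect + per-sample column effect.
    """
    groups = probe_gene_groups(probe_matrix)
    if not groups:
        raise ValueError("no probe groups found")
    genes = list(groups)
    out = np.empty((len(genes), probe_matrix.n_samples))
    for i, gene in enumerate(genes):
        idx = groups[gene]
        if not idx:
            raise ValueError(f"empty probe group for gene {gene!r}")
        sub = probe_matrix.values[idx, :]
        overall, _row, colfx, _res = median_polish(sub)
        out[i, :] = overall + colfx
    logger.info("median polish summarised %d probes into %d genes",
                probe_matrix.n_genes, len(genes))
    return ExpressionMatrix(out, genes, list(probe_matrix.sample_ids))
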