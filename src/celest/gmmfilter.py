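"""Adaptive two-step gene filtering via 1-D Gaussian-mixture decomposition.

Rather than dropping a fixed fraction of low-signal genes, the per-gene
summary statistic (mean log2 expression, then log variance) is decomposed
into Gaussian components and whole components are kept or rejected:

* amplitude step — fit a mixture to per-gene mean expression and keep the
  genes assigned to the (up to) three components with the highest means;
* variance step — fit a mixture to log per-gene variance and reject the
  genes assigned to the lowest-mean (lowest-variance) component.

Component count is chosen by BIC; assignment is hard maximum a posteriori.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .core_io import ExpressionMatrix, FilterConfig

logger = logging.getLogger("celest")


@dataclass
class GaussianMixture1D:
    """A fitted 1-D Gaussian mixture, components sorted by mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n_iter: int = 0
    ll_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, float)[order]
        self.means = np.asarray(self.means, float)[order]
        self.variances = np.asarray(self.variances, float)[order]
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("mixture variances must be positive")

    def bic(self, n: int) -> float:
        n_params = 3 * self.k - 1
        return n_params * np.log(n) - 2.0 * self.log_likelihood

    def responsibilities(self, values: np.ndarray) -> np.ndarray:
        log_dens = (
            np.log(self.weights)[None, :]
            + norm.logpdf(values[:, None], self.means[None, :],
                          np.sqrt(self.variances)[None, :])
        )
        log_dens -= log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens)
        return dens / dens.sum(axis=1, keepdims=True)

    def map_component(self, values: np.ndarray) -> np.ndarray:
        """Hard MAP component index (into the mean-sorted components)."""
        return self.responsibilities(values).argmax(axis=1)


def _em_once(
    values: np.ndarray,
    means0: np.ndarray,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> GaussianMixture1D:
    k = means0.size
    n = values.size
    w = np.full(k, 1.0 / k)
    mu = means0.astype(float).copy()
    var = np.full(k, max(values.var(), var_floor))
    ll_prev = -np.inf
    trace = []
    log2pi = np.log(2.0 * np.pi)
    for it in range(max_iter):
        logd = (
            np.log(w)[None, :]
            - 0.5 * (log2pi + np.log(var))[None, :]
            - 0.5 * (values[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        mx = logd.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logd - mx).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logd - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if ll - ll_prev < tol and it > 0:
            break
        ll_prev = ll
    return GaussianMixture1D(
        k=k, weights=w, means=mu, variances=var, log_likelihood=ll,
        n_iter=it + 1, ll_trace=np.asarray(trace),
    )


def _kmeans_like_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding of initial component means."""
    centres = [values[rng.integers(values.size)]]
    for _ in range(k - 1):
        d2 = np.min((values[:, None] - np.asarray(centres)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centres.append(values[rng.integers(values.size)])
            continue
        centres.append(values[rng.choice(values.size, p=d2 / total)])
    return np.sort(np.asarray(centres))


def fit_gmm_1d(
    values: Sequence[float] | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GaussianMixture1D:
    """EM fit of a k-component 1-D Gaussian mixture.

    Best of ``n_restarts`` seeded k-means++-style initialisations, run to
    log-likelihood convergence with a variance floor of 1e-6 times the
    sample variance.  Requires at least 10*k observations.
    """
    values = np.asarray(values, float).ravel()
    if values.size < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}")
    if np.ptp(values) == 0.0:
        if k == 1:
            return GaussianMixture1D(
                k=1, weights=np.array([1.0]), means=np.array([values[0]]),
                variances=np.array([1e-12]), log_likelihood=float("inf"),
            )
        raise ValueError("degenerate (constant) values: only k=1 is fittable")
    var_floor = 1e-6 * values.var()
    rng = np.random.default_rng(seed)
    best: GaussianMixture1D | None = None
    for _ in range(n_restarts):
        means0 = _kmeans_like_init(values, k, rng)
        fit = _em_once(values, means0, var_floor, tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def select_components(
    values: Sequence[float] | np.ndarray,
    k_range: Iterable[int] = (1, 2, 3, 4, 5, 6),
    seed: int = 0,
    n_restarts: int = 10,
) -> GaussianMixture1D:
    """Fit mixtures across ``k_range`` and return the minimum-BIC model
    (ties broken toward the smaller k)."""
    values = np.asarray(values, float).ravel()
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    best: GaussianMixture1D | None = None
    best_bic = np.inf
    for k in ks:
        if values.size < 10 * k:
            continue
        fit = fit_gmm_1d(values, k, seed=seed, n_restarts=n_restarts)
        bic = fit.bic(values.size)
        if bic < best_bic - 1e-12:
            best, best_bic = fit, bic
    if best is None:
        raise ValueError("no k in k_range is fittable for this sample size")
    return best


def amplitude_filter(
    matrix: ExpressionMatrix,
    config: FilterConfig | None = None,
    seed: int = 0,
) -> tuple[list[str], GaussianMixture1D]:
    """Keep genes in the highest-amplitude mixture components.

    The per-gene statistic is the mean log2 expression across samples.
    After BIC model selection, genes MAP-assigned to the min(3, k-1)
    highest-mean components are retained; a k=1 fit keeps everything.
    """
    cfg = config or FilterConfig()
    stat = matrix.values.mean(axis=1)
    model = select_components(stat, cfg.k_range, seed=seed, n_restarts=cfg.n_restarts)
    if model.k <= 1:
        warnings.warn("amplitude filter: single-component fit, keeping all genes")
        return list(matrix.gene_ids), model
    n_keep = min(cfg.n_keep_amplitude, model.k - 1)
    keep_components = set(range(model.k - n_keep, model.k))  # highest means
    assign = model.map_component(stat)
    kept = [g for g, c in zip(matrix.gene_ids, assign) if c in keep_components]
    logger.info("amplitude filter: kept %d / %d genes (k=%d, keeping top %d components)",
                len(kept), matrix.n_genes, model.k, n_keep)
    return kept, model


def variance_filter(
    matrix: ExpressionMatrix,
    config: FilterConfig | None = None,
    seed: int = 0,
) -> tuple[list[str], GaussianMixture1D | None]:
    """Reject genes in the lowest-variance mixture component.

    The statistic is log per-gene sample variance; genes with zero
    variance go straight to the removal set.  A k=1 fit removes nothing.
    """
    if matrix.n_samples < 2:
        raise ValueError("variance filter needs >= 2 samples")
    cfg = config or FilterConfig()
    var = matrix.values.var(axis=1, ddof=1)
    zero = var <= 0
    logvar = np.log(var[~zero])
    if logvar.size == 0:
        return [], None
    model = select_components(logvar, cfg.k_range, seed=seed, n_restarts=cfg.n_restarts)
    nonzero_ids = [g for g, z in zip(matrix.gene_ids, zero) if not z]
    if model.k <= 1:
        warnings.warn("variance filter: single-component fit, removing nothing")
        return nonzero_ids, model
    assign = model.map_component(logvar)
    kept = [g for g, c in zip(nonzero_ids, assign) if c != 0]  # drop lowest-mean comp
    logger.info("variance filter: kept %d / %d genes (k=%d)",
                len(kept), matrix.n_genes, model.k)
    return kept, model
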