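"""Synthetic multi-class, multi-batch expression data with planted truth.

The generator emulates the structure of a large multicentre leukaemia
expression cohort: ~10^4 genes on a log2 scale, 18 unbalanced disease
classes, 11 preparation-centre batches with additive and multiplicative
per-gene effects, a low-intensity background component among the per-gene
baselines, planted class-enhanced differential genes and single-class
biomarkers, and optionally heavy-tailed residual noise in some classes.

The generative model for gene g in sample s of class k and batch b is

    x_{g,s} = mu_g + beta_{g,k} + gamma_{g,b} + delta_{g,b} * eps_{g,s}

with mu_g drawn from a 4-component Gaussian mixture (one low "background"
component plus three signal components), gamma additive batch shifts,
delta multiplicative batch scale factors with mean 1, and eps residual
noise (Gaussian, or scaled t with 3 df in designated heavy-tail classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleAnnotation, SUBTYPE_SIZES, SUBTYPE_TO_MAIN


def _default_class_sizes() -> dict[str, int]:
    """The 18-class cohort profile scaled down ~10x with a floor of 10."""
    return {c: max(10, round(n / 10)) for c, n in SUBTYPE_SIZES.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions at desk scale: the unbalanced
    18-class profile (scaled down tenfold, minimum 10 samples per class),
    11 batches, a four-component log2 baseline mixture whose lowest-mean
    component is non-informative background, and residual noise of 0.5 on
    the log2 scale with planted effects of 1.5.
    """

    n_genes: int = 10_000
    class_sizes: dict[str, int] = field(default_factory=_default_class_sizes)
    n_batches: int = 11
    #: (weights, means, sds) of the baseline mixture; first component is the
    #: low-intensity background.
    baseline_weights: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    baseline_means: tuple[float, ...] = (4.0, 6.5, 8.5, 10.5)
    baseline_sds: tuple[float, ...] = (0.35, 0.6, 0.6, 0.7)
    effect_size: float = 1.5
    n_ce_degs: int = 100
    n_biomarkers_per_class: int = 5
    batch_sd_add: float = 0.5
    batch_scale_shape: float = 50.0
    batch_affected_fraction: float = 1.0
    noise_sd: float = 0.5
    #: residual SD multiplier for background genes (low variance)
    background_noise_factor: float = 0.3
    heavy_tail_classes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.baseline_weights, float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("baseline mixture weights must sum to 1")
        if not (len(self.baseline_weights) == len(self.baseline_means) == len(self.baseline_sds)):
            raise ValueError("baseline mixture parameter lengths differ")
        if self.n_genes <= 0 or self.n_batches <= 0:
            raise ValueError("n_genes and n_batches must be positive")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be positive")
        if sum(self.class_sizes.values()) == 0:
            raise ValueError("class sizes sum to 0")
        unknown = set(self.heavy_tail_classes) - set(self.class_sizes)
        if unknown:
            raise ValueError(f"heavy_tail_classes not in class set: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Per-gene planted truth, aligned with the simulated matrix rows."""

    table: pd.DataFrame  # index gene_id; columns below

    @property
    def is_background(self) -> pd.Series:
        return self.table["is_background"]

    @property
    def ce_deg_classes(self) -> pd.Series:
        """Semicolon-joined class labels the gene separates ('' if none)."""
        return self.table["ce_deg_classes"]

    @property
    def biomarker_class(self) -> pd.Series:
        return self.table["biomarker_class"]

    @property
    def batch_affected(self) -> pd.Series:
        return self.table["batch_affected"]

    def ce_deg_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, classes in self.ce_deg_classes.items():
            for c in filter(None, classes.split(";")):
                out.setdefault(c, set()).add(gene)
        return out

    def biomarker_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, c in self.biomarker_class.items():
            if c:
                out.setdefault(c, set()).add(gene)
        return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Simulate a matrix, annotation and ground truth under ``config``.

    Planted biomarker genes receive a +/- ``effect_size`` shift in exactly
    one class; planted two-class CE-DEGs receive opposite shifts in two
    classes (so each of those classes separates from every other class,
    but the gene is unique to neither).  Background genes draw their
    baseline from the lowest-mean mixture component and get reduced
    residual variance.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_sizes)
    sizes = [cfg.class_sizes[c] for c in classes]
    n_samples = int(sum(sizes))
    n_genes = cfg.n_genes

    class_of = np.repeat(np.arange(len(classes)), sizes)
    # batches assigned round-robin after a seeded shuffle: every batch mixes
    # classes, so batch and class are not confounded
    batch_of = np.arange(n_samples) % cfg.n_batches
    rng.shuffle(batch_of)

    # --- baselines from the mixture; component 0 is background ------------
    weights = np.asarray(cfg.baseline_weights, float)
    comp = rng.choice(len(weights), size=n_genes, p=weights)
    mu = rng.normal(
        np.asarray(cfg.baseline_means, float)[comp],
        np.asarray(cfg.baseline_sds, float)[comp],
    )
    is_background = comp == 0

    # --- planted class effects --------------------------------------------
    signal_genes = np.flatnonzero(~is_background)
    n_bio_total = cfg.n_biomarkers_per_class * len(classes)
    n_planted = n_bio_total + cfg.n_ce_degs
    if cfg.effect_size != 0.0 and n_planted > signal_genes.size:
        raise ValueError("not enough signal genes to plant the requested effects")
    beta = np.zeros((n_genes, len(classes)))
    ce_deg_classes = ["" for _ in range(n_genes)]
    biomarker_class = ["" for _ in range(n_genes)]

    if cfg.effect_size != 0.0:
        chosen = rng.choice(signal_genes, size=n_planted, replace=False)
        bio_genes = chosen[:n_bio_total]
        ce_genes = chosen[n_bio_total:]
        for i, g in enumerate(bio_genes):
            k = i % len(classes)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            beta[g, k] = sign * cfg.effect_size
            biomarker_class[g] = classes[k]
            ce_deg_classes[g] = classes[k]
        for g in ce_genes:
            k1, k2 = rng.choice(len(classes), size=2, replace=False)
            beta[g, k1] = cfg.effect_size
            beta[g, k2] = -cfg.effect_size
            ce_deg_classes[g] = ";".join(sorted([classes[k1], classes[k2]]))

    # --- batch effects ----------------------------------------------------
    batch_affected = rng.random(n_genes) < cfg.batch_affected_fraction
    if cfg.batch_sd_add == 0.0:
        batch_affected = np.zeros(n_genes, dtype=bool)
    gamma = rng.normal(0.0, cfg.batch_sd_add, size=(n_genes, cfg.n_batches))
    gamma[~batch_affected, :] = 0.0
    if cfg.batch_scale_shape > 0:
        delta = rng.gamma(cfg.batch_scale_shape, 1.0 / cfg.batch_scale_shape,
                          size=(n_genes, cfg.n_batches))
        delta[~batch_affected, :] = 1.0
    else:
        delta = np.ones((n_genes, cfg.n_batches))

    # --- residual noise ----------------------------------------------------
    eps = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    heavy = np.isin(class_of, [classes.index(c) for c in cfg.heavy_tail_classes])
    if heavy.any():
        # t(3) scaled to unit SD, so noise_sd keeps its meaning
        t_draws = rng.standard_t(3, size=(n_genes, int(heavy.sum()))) / np.sqrt(3.0)
        eps[:, heavy] = t_draws
    sd_per_gene = np.where(is_background,
                           cfg.noise_sd * cfg.background_noise_factor,
                           cfg.noise_sd)
    eps *= sd_per_gene[:, None]

    values = (
        mu[:, None]
        + beta[:, class_of]
        + gamma[:, batch_of]
        + delta[:, batch_of] * eps
    )

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    matrix = ExpressionMatrix(values, gene_ids, sample_ids)

    ann = pd.DataFrame(
        {
            "subtype": [classes[k] for k in class_of],
            "batch": [f"b{b:02d}" for b in batch_of],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if set(classes) <= set(SUBTYPE_TO_MAIN):
        ann["main_class"] = ann["subtype"].map(SUBTYPE_TO_MAIN)
    else:
        ann["main_class"] = ann["subtype"]
    annotation = SampleAnnotation(ann)

    truth = GroundTruth(
        pd.DataFrame(
            {
                "is_background": is_background,
                "ce_deg_classes": ce_deg_classes,
                "biomarker_class": biomarker_class,
                "batch_affected": batch_affected,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return matrix, annotation, truth


def simulate_probe_matrix(
    summary: ExpressionMatrix,
    probes_per_gene: int,
    affinity_sd: float,
    seed: int,
    noise_sd: float = 0.0,
) -> ExpressionMatrix:
    """Expand a gene-level matrix to probe level.

    Each probe value is its gene's value plus a fixed probe affinity (drawn
    once per probe, centred to sum to zero within each gene) plus optional
    measurement noise.  Probe rows are labelled ``<gene>::p<i>`` so the
    gene grouping is recoverable from the id.
    """
    if probes_per_gene < 2:
        raise ValueError("probes_per_gene must be >= 2")
    rng = np.random.default_rng(seed)
    g, s = summary.values.shape
    affinity = rng.normal(0.0, affinity_sd, size=(g, probes_per_gene))
    # centre on the lower median: summaries of a median polish are then
    # unbiased for the gene values, and the affinities still sum to ~0
    low_med = np.sort(affinity, axis=1)[:, (probes_per_gene - 1) // 2]
    affinity -= low_med[:, None]
    probe_values = (
        np.repeat(summary.values, probes_per_gene, axis=0)
        + np.repeat(affinity.reshape(-1), s).reshape(-1, s)
    )
    if noise_sd > 0:
        probe_values = probe_values + rng.normal(0.0, noise_sd, size=probe_values.shape)
    probe_ids = [
        f"{gene}::p{i}" for gene in summary.gene_ids for i in range(probes_per_gene)
    ]
    return ExpressionMatrix(probe_values, probe_ids, list(summary.sample_ids))


def probe_gene_groups(probe_matrix: ExpressionMatrix) -> dict[str, list[int]]:
    """Map gene id -> probe row indices for a ``<gene>::p<i>``-labelled matrix."""
    groups: dict[str, list[int]] = {}
    for i, pid in enumerate(probe_matrix.gene_ids):
        gene = pid.rsplit("::", 1)[0]
        groups.setdefault(gene, []).append(i)
    return groups


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")


def read_ground_truth(path) -> GroundTruth:
    table = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    table["is_background"] = table["is_background"].astype(str).str.lower() == "true"
    table["batch_affected"] = table["batch_affected"].astype(str).str.lower() == "true"
    return GroundTruth(table)
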