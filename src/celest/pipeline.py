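"""End-to-end pipeline orchestration with per-stage gene-count logging.

Order of stages: (optional probe-level preprocessing) -> batch adjustment
-> adaptive amplitude filter -> adaptive variance filter -> the three
comparative analyses (main types vs control; main-type all-pairs; subtype
all-pairs) -> marker reports -> optional cross-validation study.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .core_io import (
    AnalysisConfig,
    ExpressionMatrix,
    SampleAnnotation,
    SUBTYPE_TO_MAIN,
    merge_to_main_classes,
)
from .batchfx import combat_adjust, kw_batch_test, pca_diagnostic
from .gmmfilter import amplitude_filter, variance_filter
from .stats import (
    anova_gate,
    games_howell_matrix,
    kruskal_wallis_gate,
    route_analysis,
)
from .markers import BiomarkerReport, case_control_degs, dice_matrix, select_biomarkers

logger = logging.getLogger("celest")


@dataclass
class PipelineReport:
    """Per-stage bookkeeping: gene counts after each reduction, timings,
    config snapshot, and the stage outputs."""

    config: AnalysisConfig
    stages: list[dict[str, Any]] = field(default_factory=list)
    outputs: dict[str, Any] = field(default_factory=dict)

    def record(self, stage: str, n_genes: int, seconds: float, **extra: Any) -> None:
        self.stages.append({"stage": stage, "n_genes": n_genes,
                            "seconds": round(seconds, 3), **extra})
        logger.info("stage %-22s genes=%-6d (%.2fs)", stage, n_genes, seconds)

    def gene_counts(self) -> list[int]:
        return [s["n_genes"] for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def run_pipeline(
    config: AnalysisConfig,
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    control: str = "CTR",
    run_cv: bool = False,
) -> PipelineReport:
    """Run batch adjustment, adaptive filtering, the three comparative
    analyses and marker selection on an already-summarised matrix.

    Analysis 1 compares each main class with the control group (routed to
    the Dunnett branch when assumptions hold); analyses 2 and 3 are
    all-pairs comparisons of main classes and of subtypes (Kruskal–Wallis
    gate plus Games–Howell post-hoc when assumptions are violated).
    Deterministic given ``config.seed``.
    """
    report = PipelineReport(config=config)
    if "main_class" not in annotation.table.columns:
        subtypes = set(annotation.subtype)
        if subtypes <= set(SUBTYPE_TO_MAIN):
            annotation = merge_to_main_classes(annotation)
        else:  # synthetic or custom class sets: each subtype is its own class
            mapping = {s: s for s in subtypes}
            annotation = merge_to_main_classes(annotation, mapping)
    annotation = annotation.aligned_to(matrix)
    alpha = config.alpha
    seed = config.seed

    t0 = time.perf_counter()
    scores, frac = pca_diagnostic(matrix, n_components=2)
    report.record("pca_diagnostic", matrix.n_genes, time.perf_counter() - t0,
                  pc1_fraction=float(frac[0]))
    report.outputs["pca_scores"] = scores

    # --- batch adjustment -------------------------------------------------
    t0 = time.perf_counter()
    batch = annotation.batch.to_numpy()
    if np.unique(batch).size >= 2:
        _, n_before = kw_batch_test(matrix, batch, alpha)
        adjusted, model = combat_adjust(matrix, batch, annotation.subtype.to_numpy())
        _, n_after = kw_batch_test(adjusted, batch, alpha)
    else:
        adjusted, model = matrix, None
        n_before = n_after = 0
    report.record("combat_adjust", adjusted.n_genes, time.perf_counter() - t0,
                  batch_sig_before=n_before, batch_sig_after=n_after)
    report.outputs["batch_model"] = model

    # --- adaptive filtering ----------------------------------------------
    t0 = time.perf_counter()
    kept_amp, amp_model = amplitude_filter(adjusted, config.filter, seed=seed)
    filtered = adjusted.subset_genes(kept_amp)
    report.record("amplitude_filter", filtered.n_genes, time.perf_counter() - t0,
                  k=amp_model.k)
    t0 = time.perf_counter()
    kept_var, var_model = variance_filter(filtered, config.filter, seed=seed)
    filtered = filtered.subset_genes(kept_var)
    report.record("variance_filter", filtered.n_genes, time.perf_counter() - t0,
                  k=var_model.k if var_model else 0)
    report.outputs["filtered_matrix"] = filtered
    report.outputs["filter_models"] = {"amplitude": amp_model, "variance": var_model}

    main = annotation.main_class.to_numpy()
    subtype = annotation.subtype.to_numpy()

    # --- analysis 1: main classes vs control ------------------------------
    t0 = time.perf_counter()
    branch1 = route_analysis(filtered, main, alpha,
                             config.test.routing_max_genes, seed=seed)
    if branch1 == "parametric":
        gated_ids, _ = anova_gate(filtered, main, alpha)
    else:
        gated_ids, _ = kruskal_wallis_gate(filtered, main, alpha)
    gated = filtered.subset_genes(gated_ids)
    degs = case_control_degs(gated, main, control=control, alpha=alpha,
                             n_draws=config.test.dunnett_mc_draws, seed=seed)
    report.record("case_control", gated.n_genes, time.perf_counter() - t0,
                  branch=branch1)
    report.outputs["case_control_degs"] = degs
    report.outputs["deg_counts"] = pd.DataFrame(
        {c: d.counts for c, d in degs.items()}
    ).T
    deg_sets = {c: d.genes for c, d in degs.items()}
    report.outputs["deg_dice"] = dice_matrix(deg_sets, universe=set(filtered.gene_ids),
                                             seed=seed)

    # --- analysis 2: main-class all-pairs ---------------------------------
    report.outputs["main_class_markers"] = _all_pairs_analysis(
        filtered, main, config, report, "main_pairs"
    )

    # --- analysis 3: subtype all-pairs ------------------------------------
    report.outputs["subtype_markers"] = _all_pairs_analysis(
        filtered, subtype, config, report, "subtype_pairs"
    )

    # --- optional CV study -------------------------------------------------
    if run_cv:
        from .cvclassify import confusion_metrics, make_ttest_selector, repeated_stratified_cv

        t0 = time.perf_counter()
        table = repeated_stratified_cv(
            filtered, subtype,
            feature_selector=make_ttest_selector(config.cv.n_top, config.cv.r_threshold),
            k=config.cv.k_folds, reps=config.cv.repetitions, seed=seed,
        )
        sens, wavg, ci = confusion_metrics(table)
        report.record("cross_validation", filtered.n_genes, time.perf_counter() - t0,
                      weighted_sensitivity=round(wavg, 4))
        report.outputs["cv_confusion"] = table
        report.outputs["cv_metrics"] = {"sensitivity": sens,
                                        "weighted": wavg, "ci": ci}
    return report


def _all_pairs_analysis(
    filtered: ExpressionMatrix,
    labels: np.ndarray,
    config: AnalysisConfig,
    report: PipelineReport,
    stage: str,
) -> BiomarkerReport:
    alpha, seed = config.alpha, config.seed
    t0 = time.perf_counter()
    branch = route_analysis(filtered, labels, alpha,
                            config.test.routing_max_genes, seed=seed)
    if branch == "parametric":
        gated_ids, _ = anova_gate(filtered, labels, alpha)
    else:
        gated_ids, _ = kruskal_wallis_gate(filtered, labels, alpha)
    gated = filtered.subset_genes(gated_ids)
    pairwise = games_howell_matrix(gated, labels, alpha)
    result = select_biomarkers(pairwise)
    report.record(stage, gated.n_genes, time.perf_counter() - t0, branch=branch)
    report.outputs[f"{stage}_pairwise"] = pairwise
    return result
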