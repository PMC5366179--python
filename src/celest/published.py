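"""Published summary tables from the Stage-I MILE leukaemia cohort.

These small printed tables (per-class differential-expression counts and
cross-validation prediction summaries) are inputs for arithmetic checks:
up/down-regulation percentages, per-class sensitivities recomputed from
diagonal counts and class totals, and weighted average sensitivities.
The raw expression data behind them are not redistributed here.
"""

from __future__ import annotations

#: Per main class: (total differentiating genes vs control, up-regulated,
#: down-regulated) from the case-control comparison.
CASE_CONTROL_DEG_COUNTS: dict[str, tuple[int, int, int]] = {
    "ALL": (6186, 3110, 3076),
    "AML": (5628, 2857, 2771),
    "CLL": (6577, 3297, 3280),
    "CML": (3791, 1509, 2282),
    "MDS": (1317, 500, 817),
}

#: Class totals (column "Total") of the 18-subgroup cross-validation
#: prediction tables, classes C1..C18 in table order.  They sum to 2096.
CV_CLASS_TOTALS: tuple[int, ...] = (
    13, 70, 237, 174, 58, 36, 40, 122, 40, 37, 28, 38, 351, 48, 448, 76, 206, 74,
)

#: Printed per-class sensitivities, original MILE preprocessing pipeline.
CV_SENSITIVITY_ORIGINAL: tuple[float, ...] = (
    0.000, 0.776, 0.858, 0.870, 0.523, 0.213, 0.217, 0.418, 0.442,
    0.667, 0.238, 0.000, 0.890, 0.000, 0.979, 0.750, 0.841, 0.167,
)

#: Printed per-class sensitivities, batch-adjusted CE-DEG pipeline.
CV_SENSITIVITY_NOVEL: tuple[float, ...] = (
    0.231, 0.971, 0.797, 0.895, 0.926, 0.861, 0.758, 0.830, 0.933,
    0.865, 1.000, 0.526, 0.899, 0.188, 0.993, 0.886, 0.866, 0.536,
)

#: Selected repetition-averaged diagonal (correct-prediction) counts from the
#: printed prediction tables, keyed by (pipeline, class index 1-based).
CV_DIAGONAL_COUNTS: dict[tuple[str, int], float] = {
    ("original", 2): 54.3,
    ("original", 3): 203.3,
    ("novel", 2): 68.0,
    ("novel", 3): 189.0,
    ("novel", 11): 28.0,
}

#: Reported weighted average cross-validation sensitivities.
CV_WEIGHTED_SENSITIVITY: dict[str, float] = {"original": 0.739, "novel": 0.861}
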