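"""Domain types, matrix/annotation I/O, class merging and run configuration.

The pipeline works on a genes-in-rows, samples-in-columns log2 expression
matrix together with a per-sample annotation carrying the disease subtype
(18 classes), the merged main class (ALL, AML, CLL, CML, MDS, CTR) and the
preparation-centre batch label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("celest")

# ---------------------------------------------------------------------------
# Study class structure: the 18 leukaemia/MDS/control subtypes, their cohort
# sizes in the Stage-I bone-marrow study, and the subtype -> main-class merge.
# ---------------------------------------------------------------------------

#: Subtype label -> number of samples in the 2096-sample Stage-I cohort.
SUBTYPE_SIZES: dict[str, int] = {
    "B-ALL t(8;14)": 13,
    "Pro-B-ALL t(11q23)": 70,
    "Pre-B-ALL t(9;22)+": 122,
    "T-ALL": 174,
    "ALL t(12;21)": 58,
    "ALL t(1;19)": 36,
    "ALL hyperdiploid": 40,
    "Pre-B-ALL t(9;22)-": 237,
    "AML t(8;21)": 40,
    "AML t(15;17)": 37,
    "AML t(16;16)": 28,
    "AML t(11q23)": 38,
    "AML normal karyotype": 351,
    "AML complex aberrant karyotype": 48,
    "CLL": 448,
    "CML": 76,
    "MDS": 206,
    "CTR": 74,
}

MAIN_CLASSES: tuple[str, ...] = ("ALL", "AML", "CLL", "CML", "MDS", "CTR")

#: Deterministic subtype -> main-class mapping (8 ALL subtypes, 6 AML
#: subtypes; CLL/CML/MDS/CTR map to themselves).
SUBTYPE_TO_MAIN: dict[str, str] = {
    "B-ALL t(8;14)": "ALL",
    "Pro-B-ALL t(11q23)": "ALL",
    "Pre-B-ALL t(9;22)+": "ALL",
    "T-ALL": "ALL",
    "ALL t(12;21)": "ALL",
    "ALL t(1;19)": "ALL",
    "ALL hyperdiploid": "ALL",
    "Pre-B-ALL t(9;22)-": "ALL",
    "AML t(8;21)": "AML",
    "AML t(15;17)": "AML",
    "AML t(16;16)": "AML",
    "AML t(11q23)": "AML",
    "AML normal karyotype": "AML",
    "AML complex aberrant karyotype": "AML",
    "CLL": "CLL",
    "CML": "CML",
    "MDS": "MDS",
    "CTR": "CTR",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities.

    ``values`` is a float array with ``gene_ids`` labelling rows and
    ``sample_ids`` labelling columns.  No missing values are allowed and
    identifiers must be unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids and {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = set(map(str, gene_ids))
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            self.values[idx, :], [self.gene_ids[i] for i in idx], list(self.sample_ids)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[str(s)] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.sample_ids[i] for i in idx]
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class SampleAnnotation:
    """Per-sample subtype / main-class / batch table.

    Wraps a DataFrame indexed by sample id with columns ``subtype``,
    ``main_class`` and ``batch``.  ``main_class`` is derived from the
    subtype, never stored on disk.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subtype", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in annotation: {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def subtype(self) -> pd.Series:
        return self.table["subtype"]

    @property
    def batch(self) -> pd.Series:
        return self.table["batch"]

    @property
    def main_class(self) -> pd.Series:
        if "main_class" not in self.table.columns:
            raise ValueError("main_class not assigned; call merge_to_main_classes first")
        return self.table["main_class"]

    def aligned_to(self, matrix: ExpressionMatrix) -> "SampleAnnotation":
        """Return annotation rows in the matrix's sample order; every matrix
        sample must have exactly one annotation row."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without annotation: {missing[:5]}")
        return SampleAnnotation(self.table.loc[matrix.sample_ids].copy())


@dataclass
class FilterConfig:
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_keep_amplitude: int = 3
    n_restarts: int = 10


@dataclass
class TestConfig:
    dunnett_mc_draws: int = 100_000
    routing_max_genes: int = 200


@dataclass
class CVConfig:
    k_folds: int = 30
    repetitions: int = 3
    n_top: int = 100
    r_threshold: float = 0.5


@dataclass
class AnalysisConfig:
    """Top-level run configuration."""

    alpha: float = 0.05
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    test: TestConfig = field(default_factory=TestConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("filter", FilterConfig), ("test", TestConfig), ("cv", CVConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# I/O — single TSV dialect: UTF-8, tab-separated, '.' decimal, no quoting
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    Raises on duplicate identifiers and on non-numeric cells, naming the
    offending row/column.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = frame.index[bad.isna().to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value at gene {row!r}, sample {col!r}"
            ) from None
    matrix = ExpressionMatrix(values, list(frame.index), list(frame.columns))
    logger.info("read matrix %s: %d genes x %d samples", path, matrix.n_genes, matrix.n_samples)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV with columns sample_id, subtype, batch."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table.columns:
        raise ValueError("annotation file must have a sample_id column")
    table = table.set_index("sample_id")
    return SampleAnnotation(table)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    out = annotation.table.drop(columns=["main_class"], errors="ignore")
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Class merging
# ---------------------------------------------------------------------------


def merge_to_main_classes(
    annotation: SampleAnnotation,
    mapping: Mapping[str, str] | None = None,
) -> SampleAnnotation:
    """Assign each sample its main class from its subtype.

    The default mapping merges the 8 ALL subtypes and the 6 AML subtypes;
    CLL, CML, MDS and CTR are their own main classes.  The number of rows
    is preserved and the operation is idempotent.
    """
    mapping = dict(mapping) if mapping is not None else SUBTYPE_TO_MAIN
    table = annotation.table.copy()
    unknown = sorted(set(table["subtype"]) - set(mapping))
    if unknown:
        raise ValueError(f"unknown subtype labels: {unknown}")
    table["main_class"] = table["subtype"].map(mapping)
    return SampleAnnotation(table)


def main_class_sizes(subtype_sizes: Mapping[str, int] | None = None) -> dict[str, int]:
    """Aggregate subtype cohort sizes into main-class sizes."""
    sizes = dict(subtype_sizes) if subtype_sizes is not None else SUBTYPE_SIZES
    out: dict[str, int] = {}
    for subtype, n in sizes.items():
        if subtype not in SUBTYPE_TO_MAIN:
            raise ValueError(f"unknown subtype label: {subtype!r}")
        out[SUBTYPE_TO_MAIN[subtype]] = out.get(SUBTYPE_TO_MAIN[subtype], 0) + int(n)
    return out
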