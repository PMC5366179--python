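"""Repeated stratified cross-validation classification study.

Features are selected inside each training fold (no leakage): either the
union of each class pair's top t-test genes, or a caller-supplied selector
(e.g. the CE-DEG machinery), followed by an effect-size decorrelation step
and a minimum-error feature-count rule.  The classifier is a linear-kernel
SVM (one-vs-one multiclass); confusion counts are accumulated per
repetition and averaged, giving fractional cells.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_io import ExpressionMatrix

logger = logging.getLogger("celest")

#: selector(train_values [samples x genes], train_labels) -> ranked feature indices
FeatureSelector = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class ConfusionTable:
    """Class x class prediction counts averaged over CV repetitions."""

    counts: pd.DataFrame  # rows: true class, columns: predicted class
    reps: int

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.counts.columns):
            raise ValueError("confusion table must be square with matching labels")

    @property
    def class_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def sensitivity(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts.values), index=self.counts.index)
        return diag / self.class_totals


def confusion_metrics(
    table: ConfusionTable, level: float = 0.95
) -> tuple[pd.Series, float, tuple[float, float]]:
    """Per-class sensitivity, weighted average sensitivity and its CI.

    The weighted average is sum(total_c * sens_c) / sum(total_c); the CI
    is the normal approximation on N_eff = reps * sum(total_c) Bernoulli
    trials.
    """
    totals = table.class_totals
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"classes with zero total: {bad}")
    sens = table.sensitivity
    w = float((totals * sens).sum() / totals.sum())
    n_eff = table.reps * float(totals.sum())
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(w * (1 - w), 0.0) / n_eff)
    return sens, w, (max(w - half, 0.0), min(w + half, 1.0))


def weighted_sensitivity(
    sensitivities: Sequence[float], totals: Sequence[float]
) -> float:
    """Class-total-weighted average of per-class sensitivities."""
    s = np.asarray(sensitivities, float)
    t = np.asarray(totals, float)
    if s.shape != t.shape or t.sum() <= 0:
        raise ValueError("sensitivities and totals must align, totals positive")
    return float((s * t).sum() / t.sum())


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def _pairwise_t_pvalues(x: np.ndarray, labels: np.ndarray, a, b) -> np.ndarray:
    xa, xb = x[labels == a], x[labels == b]
    res = sps.ttest_ind(xa, xb, axis=0, equal_var=True)
    return np.nan_to_num(res.pvalue, nan=1.0)


def ttest_top_union(
    values: np.ndarray, labels: np.ndarray, n_top: int = 100
) -> np.ndarray:
    """Union of each class pair's top ``n_top`` genes by two-sample t-test.

    ``values`` is samples x genes.  Returns feature indices ordered by
    their best (smallest) pairwise p-value.
    """
    labels = np.asarray(labels)
    levs = sorted(set(map(str, labels)))
    if len(levs) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((labels == c).sum()) for c in levs}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"classes with < 2 samples: {small}")
    best = np.full(values.shape[1], np.inf)
    chosen: set[int] = set()
    for a, b in itertools.combinations(levs, 2):
        p = _pairwise_t_pvalues(values, labels.astype(str), a, b)
        top = np.argsort(p, kind="stable")[: min(n_top, p.size)]
        chosen.update(top.tolist())
        best = np.minimum(best, p)
    idx = np.array(sorted(chosen))
    return idx[np.argsort(best[idx], kind="stable")]


def decorrelate_features(
    candidates: Sequence[int],
    values: np.ndarray,
    r_threshold: float = 0.5,
) -> np.ndarray:
    """Greedy decorrelation scan preserving priority order.

    Walk the ranked candidates and keep a gene iff its absolute Pearson
    correlation with every already-kept gene is below ``r_threshold``
    (|r| at or above the threshold marks a large effect-size dependence).
    """
    kept: list[int] = []
    x = values
    for c in candidates:
        col = x[:, c]
        if np.std(col) == 0:
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(col, x[:, k])[0, 1]
            if np.abs(r) >= r_threshold:
                ok = False
                break
        if ok:
            kept.append(int(c))
    return np.asarray(kept, dtype=int)


DEFAULT_COUNT_GRID: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


def min_error_feature_count(
    ranked: Sequence[int],
    values: np.ndarray,
    labels: np.ndarray,
    grid: Sequence[int] | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Minimum-error-rate choice of how many top-ranked features to keep.

    For each prefix size on the grid, the CV misclassification error of a
    linear SVM is estimated; ties go to the smallest size.  Returns
    (chosen count, error curve indexed by prefix size).
    """
    ranked = np.asarray(list(ranked), dtype=int)
    if ranked.size == 0:
        raise ValueError("ranked feature list is empty")
    grid = [g for g in (grid if grid is not None else DEFAULT_COUNT_GRID) if g <= ranked.size]
    if not grid and ranked.size:
        grid = [ranked.size]
    if not grid:
        raise ValueError("empty feature-count grid")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    k_eff = int(min(k_folds, counts.min()))
    if k_eff < 2:
        raise ValueError("smallest class too small for internal CV")
    errors = {}
    for size in grid:
        feats = ranked[:size]
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        wrong = 0
        for tr, te in skf.split(values, labels):
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(values[np.ix_(tr, feats)], labels[tr])
            wrong += int((clf.predict(values[np.ix_(te, feats)]) != labels[te]).sum())
        errors[size] = wrong / labels.size
    curve = pd.Series(errors).sort_index()
    chosen = int(curve.index[np.argmin(curve.values)])  # argmin takes first -> smallest
    return chosen, curve


def make_ttest_selector(n_top: int = 100, r_threshold: float = 0.5) -> FeatureSelector:
    """Training-fold selector: top-t-test union followed by decorrelation."""

    def select(train_values: np.ndarray, train_labels: np.ndarray) -> np.ndarray:
        ranked = ttest_top_union(train_values, train_labels, n_top=n_top)
        return decorrelate_features(ranked, train_values, r_threshold=r_threshold)

    return select


# ---------------------------------------------------------------------------
# Repeated stratified CV
# ---------------------------------------------------------------------------


def repeated_stratified_cv(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    feature_selector: FeatureSelector | None = None,
    k: int = 30,
    reps: int = 3,
    seed: int = 0,
    C: float = 1.0,
) -> ConfusionTable:
    """k-fold stratified CV repeated ``reps`` times with a linear SVM.

    Feature selection runs inside each training fold only.  Classes with
    fewer samples than k appear in a subset of test folds; a fold whose
    training part loses a class entirely is redrawn with a fresh seed (at
    most 10 attempts).  Confusion counts are summed per repetition and
    divided by ``reps``.
    """
    labels = np.asarray(labels).astype(str)
    levs = sorted(set(labels))
    x = matrix.values.T  # samples x genes
    total = np.zeros((len(levs), len(levs)))
    pos = {c: i for i, c in enumerate(levs)}
    for rep in range(reps):
        counts = _one_repetition(x, labels, levs, pos, feature_selector, k,
                                 seed * 1009 + rep, C)
        total += counts
    frame = pd.DataFrame(total / reps, index=levs, columns=levs)
    return ConfusionTable(counts=frame, reps=reps)


def _one_repetition(
    x: np.ndarray,
    labels: np.ndarray,
    levs: list[str],
    pos: dict[str, int],
    feature_selector: FeatureSelector | None,
    k: int,
    seed: int,
    C: float,
) -> np.ndarray:
    n = labels.size
    k_eff = min(k, n)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed + attempt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # classes smaller than k
            folds = list(skf.split(np.zeros(n), labels))
        if all(set(levs) == set(labels[tr]) for tr, _ in folds):
            break
        warnings.warn("fold with an empty training class; redrawing")
    else:
        raise RuntimeError("could not build folds with all classes in training")
    counts = np.zeros((len(levs), len(levs)))
    for tr, te in folds:
        xt, yt = x[tr], labels[tr]
        if feature_selector is not None:
            feats = np.asarray(feature_selector(xt, yt), dtype=int)
            if feats.size == 0:
                feats = np.arange(x.shape[1])
        else:
            feats = np.arange(x.shape[1])
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(xt[:, feats], yt)
        pred = clf.predict(x[np.ix_(te, feats)])
        for yi, pi in zip(labels[te], pred):
            counts[pos[yi], pos[pi]] += 1
    return counts
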