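"""DEG, class-enhanced DEG (CE-DEG) and biomarker selection, plus set
similarity and enrichment statistics.

A CE-DEG for class c is a gene whose post-hoc adjusted p-value is below
alpha for every pair (c, c') — it separates c from each other class.  A
biomarker for c is a CE-DEG for c that additionally shows no significant
difference between any pair of the remaining classes, which makes
biomarker sets disjoint across classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio

from .core_io import ExpressionMatrix
from .stats import PairwiseSignificance, dunnett_matrix

logger = logging.getLogger("celest")


@dataclass
class DEGSet:
    """Differentially expressed genes of one class vs the reference, split
    by direction of change."""

    label: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    @property
    def counts(self) -> dict[str, int]:
        total = len(self.up) + len(self.down)
        return {
            "total": total,
            "up": len(self.up),
            "down": len(self.down),
            "up_pct": 100.0 * len(self.up) / total if total else 0.0,
            "down_pct": 100.0 * len(self.down) / total if total else 0.0,
        }


@dataclass
class BiomarkerReport:
    """Per-class CE-DEG and biomarker sets; biomarker(c) is a subset of
    CE-DEG(c) and biomarker sets are pairwise disjoint."""

    ce_degs: dict[str, set[str]]
    biomarkers: dict[str, set[str]]

    def __post_init__(self) -> None:
        for c, bio in self.biomarkers.items():
            if not bio <= self.ce_degs.get(c, set()):
                raise ValueError(f"biomarker set of {c!r} not within its CE-DEG set")
        classes = list(self.biomarkers)
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                if self.biomarkers[a] & self.biomarkers[b]:
                    raise ValueError(f"biomarker sets of {a!r} and {b!r} overlap")

    def summary(self) -> pd.DataFrame:
        classes = sorted(self.ce_degs)
        return pd.DataFrame(
            {
                "n_ce_degs": [len(self.ce_degs[c]) for c in classes],
                "n_biomarkers": [len(self.biomarkers.get(c, set())) for c in classes],
            },
            index=classes,
        )


# ---------------------------------------------------------------------------
# Case-control DEGs (Dunnett branch)
# ---------------------------------------------------------------------------


def case_control_degs(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    control: str = "CTR",
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
) -> dict[str, DEGSet]:
    """Per-class DEG sets vs the control group.

    A gene belongs to class c's set iff its Dunnett-adjusted p for (c vs
    control) is below alpha; the direction is the sign of the class-mean
    minus control-mean difference.
    """
    labels = np.asarray(labels)
    if control not in set(map(str, labels)):
        raise ValueError(f"control class {control!r} absent from labels")
    p, sign = dunnett_matrix(matrix, labels, control, n_draws=n_draws, seed=seed)
    out: dict[str, DEGSet] = {}
    for c in p.columns:
        sig = p[c] < alpha
        up = set(p.index[sig & (sign[c] > 0)])
        down = set(p.index[sig & (sign[c] < 0)])
        out[c] = DEGSet(label=c, up=up, down=down)
        logger.info("case-control %s: %d DEGs (%d up / %d down)",
                    c, len(up) + len(down), len(up), len(down))
    return out


# ---------------------------------------------------------------------------
# CE-DEG and biomarker selection from pairwise post-hoc results
# ---------------------------------------------------------------------------


def ce_deg_sets(
    pairwise: PairwiseSignificance, alpha: float | None = None
) -> dict[str, set[str]]:
    """CE-DEG(c) = genes significant for every pair (c, c')."""
    alpha = pairwise.alpha if alpha is None else alpha
    dec = pairwise.p < alpha
    out: dict[str, set[str]] = {}
    for c in pairwise.classes:
        cols = pairwise.pairs_of(c)
        missing = [col for col in cols if col not in dec.columns]
        if missing:
            raise ValueError(f"missing pairwise results: {missing}")
        out[c] = set(dec.index[dec[cols].all(axis=1)])
    return out


def select_biomarkers(
    pairwise: PairwiseSignificance, alpha: float | None = None
) -> BiomarkerReport:
    """Biomarker(c) = CE-DEG(c) genes with no significant difference
    between any pair of the remaining classes."""
    alpha = pairwise.alpha if alpha is None else alpha
    ce = ce_deg_sets(pairwise, alpha)
    dec = pairwise.p < alpha
    biomarkers: dict[str, set[str]] = {}
    for c in pairwise.classes:
        rest = pairwise.pairs_excluding(c)
        missing = [col for col in rest if col not in dec.columns]
        if missing:
            raise ValueError(f"missing pairwise results: {missing}")
        if rest:
            quiet = set(dec.index[~dec[rest].any(axis=1)])
        else:
            quiet = set(dec.index)
        biomarkers[c] = ce[c] & quiet
    return BiomarkerReport(ce_degs=ce, biomarkers=biomarkers)


# ---------------------------------------------------------------------------
# Set similarity
# ---------------------------------------------------------------------------


def dice_coefficient(a: set, b: set) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return 2.0 * len(set(a) & set(b)) / (len(set(a)) + len(set(b)))


def dice_confidence_interval(
    a: set,
    b: set,
    universe: set,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the Dice coefficient.

    Universe genes are resampled with replacement; membership of A and B
    follows each resampled gene (multiset counting), and the Dice value
    is recomputed per replicate.  Deterministic given the seed.
    """
    universe = sorted(universe)
    if not universe:
        raise ValueError("empty universe")
    if not (set(a) <= set(universe) and set(b) <= set(universe)):
        raise ValueError("A and B must be subsets of the universe")
    in_a = np.array([g in a for g in universe])
    in_b = np.array([g in b for g in universe])
    rng = np.random.default_rng(seed)
    n = len(universe)
    vals = np.empty(n_boot)
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        na = int(in_a[idx].sum())
        nb = int(in_b[idx].sum())
        nab = int((in_a[idx] & in_b[idx]).sum())
        vals[r] = 2.0 * nab / (na + nb) if (na + nb) else 0.0
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def dice_matrix(
    sets: dict[str, set[str]],
    universe: set[str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Dice coefficients (with bootstrap CIs if a universe is
    given) for a family of gene sets; long-format DataFrame."""
    rows = []
    names = sorted(sets)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            d = dice_coefficient(sets[x], sets[y])
            row = {"set_a": x, "set_b": y, "dsc": d}
            if universe is not None:
                lo, hi = dice_confidence_interval(
                    sets[x], sets[y], universe, n_boot=n_boot, seed=seed
                )
                row.update(ci_low=lo, ci_high=hi)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher-exact overrepresentation with user-supplied term sets
# ---------------------------------------------------------------------------


def fisher_enrichment(
    query: set[str],
    universe: set[str],
    terms: dict[str, set[str]],
) -> pd.DataFrame:
    """Two-sided Fisher exact overrepresentation of ``query`` in each term.

    The 2x2 table crosses query membership with term membership over the
    universe.  Reports the exact p and the conditional maximum-likelihood
    odds ratio (infinite odds ratios are flagged in an ``or_infinite``
    column).  Terms that do not intersect the universe are skipped with a
    warning.  Output sorted by p ascending.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    nu = len(universe)
    nq = len(query)
    for name, genes in terms.items():
        term = set(genes) & universe
        if not term:
            warnings.warn(f"term {name!r} does not intersect the universe; skipped")
            continue
        a = len(query & term)
        bq = nq - a
        c = len(term) - a
        d = nu - nq - c
        table = np.array([[a, bq], [c, d]])
        p = fisher_exact(table, alternative="two-sided")[1]
        if bq == 0 or c == 0:
            orat, inf = np.inf, True
        elif a == 0 or d == 0:
            orat, inf = 0.0, False
        else:
            orat, inf = float(odds_ratio(table, kind="conditional").statistic), False
        rows.append({
            "term": name, "n_term": len(term), "n_overlap": a,
            "p": float(p), "odds_ratio": orat, "or_infinite": inf,
        })
    return pd.DataFrame(rows).sort_values("p", ignore_index=True) if rows else pd.DataFrame(
        columns=["term", "n_term", "n_overlap", "p", "odds_ratio", "or_infinite"]
    )
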