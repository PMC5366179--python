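"""Per-gene multi-group testing.

The testing branch is routed by assumption checks: if the groups look
Gaussian with homogeneous variances the parametric branch is used (one-way
ANOVA gate, then Dunnett many-to-one against the control); otherwise the
non-parametric branch (Kruskal–Wallis gate, then Games–Howell pairwise
post-hoc with Welch degrees of freedom and the studentized-range
distribution).  All post-hoc p-values are family-wise adjusted within a
gene; no additional across-gene multiplicity correction is applied.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ExpressionMatrix
from .batchfx import kruskal_wallis_pvalues

logger = logging.getLogger("celest")


# ---------------------------------------------------------------------------
# Group container
# ---------------------------------------------------------------------------


@dataclass
class GroupSamples:
    """Value vectors of one gene split by group label."""

    labels: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("group labels must be unique")
        self.values = [np.asarray(v, float).ravel() for v in self.values]

    @classmethod
    def from_labels(cls, row: np.ndarray, labels: np.ndarray) -> "GroupSamples":
        levs = list(dict.fromkeys(labels))  # preserve first-seen order
        return cls(
            labels=[str(lev) for lev in levs],
            values=[np.asarray(row)[np.asarray(labels) == lev] for lev in levs],
        )

    @property
    def k(self) -> int:
        return len(self.labels)

    def n(self) -> np.ndarray:
        return np.array([v.size for v in self.values])

    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    def variances(self) -> np.ndarray:
        return np.array([v.var(ddof=1) if v.size > 1 else 0.0 for v in self.values])


def pair_key(a: str, b: str) -> str:
    """Canonical unordered-pair column name."""
    return "|".join(sorted((str(a), str(b))))


@dataclass
class PairwiseSignificance:
    """Gene x class-pair adjusted p-values with mean-difference signs.

    ``p`` and ``sign`` are DataFrames indexed by gene id with one column
    per unordered class pair (``pair_key`` names).  ``sign`` holds the
    sign of mean(first-alphabetical class) - mean(second)."""

    p: pd.DataFrame
    sign: pd.DataFrame
    classes: list[str]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if ((self.p.values < -1e-12) | (self.p.values > 1 + 1e-12)).any():
            raise ValueError("adjusted p-values outside [0, 1]")

    def decisions(self) -> pd.DataFrame:
        return self.p < self.alpha

    def pairs_of(self, cls: str) -> list[str]:
        return [pair_key(cls, o) for o in self.classes if o != cls]

    def pairs_excluding(self, cls: str) -> list[str]:
        return [
            pair_key(a, b)
            for a, b in itertools.combinations(sorted(self.classes), 2)
            if cls not in (a, b)
        ]


# ---------------------------------------------------------------------------
# Assumption checks and routing
# ---------------------------------------------------------------------------


def assumption_checks(groups: GroupSamples, alpha: float = 0.05) -> dict[str, bool]:
    """Shapiro–Wilk normality per group and Brown–Forsythe homoscedasticity.

    ``normal`` is True iff every group's Shapiro–Wilk p is >= alpha; a
    group with fewer than 3 observations (or constant values) cannot be
    assessed and counts as non-normal.  ``homoscedastic`` uses the
    median-centred Levene test across groups.
    """
    normal = True
    for v in groups.values:
        if v.size < 3 or np.ptp(v) == 0.0:
            normal = False
            break
        if sps.shapiro(v).pvalue < alpha:
            normal = False
            break
    usable = [v for v in groups.values if v.size >= 2]
    if len(usable) < 2 or all(np.ptp(np.concatenate(usable)) == 0.0 for _ in (0,)):
        homosced = True
    else:
        try:
            homosced = bool(sps.levene(*usable, center="median").pvalue >= alpha)
        except ValueError:
            homosced = True
    return {"normal": bool(normal), "homoscedastic": bool(homosced)}


def route_analysis(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    alpha: float = 0.05,
    max_genes: int = 200,
    seed: int = 0,
) -> str:
    """Choose 'parametric' or 'nonparametric' for a whole analysis.

    Assumption checks are run gene by gene (on a seeded subsample of at
    most ``max_genes`` genes); the parametric branch is chosen iff at
    least half the checked genes satisfy both normality and variance
    homogeneity.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(matrix.n_genes)
    if idx.size > max_genes:
        idx = np.sort(rng.choice(idx, size=max_genes, replace=False))
    labels = np.asarray(labels)
    passed = 0
    for i in idx:
        checks = assumption_checks(GroupSamples.from_labels(matrix.values[i], labels), alpha)
        passed += checks["normal"] and checks["homoscedastic"]
    frac = passed / idx.size
    branch = "parametric" if frac >= 0.5 else "nonparametric"
    logger.info("assumption routing: %.1f%% of %d genes pass both checks -> %s",
                100 * frac, idx.size, branch)
    return branch


# ---------------------------------------------------------------------------
# Gates: one-way ANOVA and Kruskal–Wallis
# ---------------------------------------------------------------------------


def oneway_anova_pvalues(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised classic one-way F-test p per row.  Rows with zero
    within-group variance and equal means get p = 1 by convention."""
    x = np.asarray(values, float)
    levs, idx = np.unique(np.asarray(labels), return_inverse=True)
    k = levs.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = x.shape[1]
    counts = np.bincount(idx).astype(float)
    sums = np.zeros((x.shape[0], k))
    for g in range(k):
        sums[:, g] = x[:, idx == g].sum(axis=1)
    grand = x.sum(axis=1) / n
    group_means = sums / counts[None, :]
    ss_between = (counts[None, :] * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ss_total = ((x - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = np.where(ss_within <= 1e-300, 1.0, sps.f.sf(f, df1, df2))
    # degenerate: no within variance but real between variance -> p ~ 0
    p = np.where((ss_within <= 1e-300) & (ss_between > 1e-300), 0.0, p)
    return p


def anova_gate(
    matrix: ExpressionMatrix, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """One-way ANOVA gate: retain genes with F-test p < alpha."""
    p = oneway_anova_pvalues(matrix.values, labels)
    series = pd.Series(p, index=matrix.gene_ids, name="anova_p")
    kept = [g for g, pi in zip(matrix.gene_ids, p) if pi < alpha]
    logger.info("ANOVA gate: %d / %d genes retained", len(kept), matrix.n_genes)
    return kept, series


def kruskal_wallis_gate(
    matrix: ExpressionMatrix, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Kruskal–Wallis gate: retain genes with tie-corrected KW p < alpha."""
    p = kruskal_wallis_pvalues(matrix.values, np.asarray(labels))
    series = pd.Series(p, index=matrix.gene_ids, name="kw_p")
    kept = [g for g, pi in zip(matrix.gene_ids, p) if pi < alpha]
    logger.info("KW gate: %d / %d genes retained", len(kept), matrix.n_genes)
    return kept, series


# ---------------------------------------------------------------------------
# Dunnett many-to-one (seeded Monte-Carlo over the equicorrelated mvt)
# ---------------------------------------------------------------------------


class DunnettNull:
    """Null distribution of max_i |T_i| for many-to-one comparisons.

    T follows the equicorrelated multivariate t with correlations
    rho_ij = lambda_i * lambda_j, lambda_i = sqrt(n_i / (n_i + n0)), and
    pooled degrees of freedom.  Sampled once (seeded Monte Carlo) and
    reused across genes, since group sizes are shared."""

    def __init__(self, n_treat: np.ndarray, n_control: int, df: int,
                 n_draws: int = 100_000, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        lam = np.sqrt(n_treat / (n_treat + n_control))
        z0 = rng.normal(size=n_draws)
        zi = rng.normal(size=(n_draws, n_treat.size))
        t = zi * np.sqrt(1 - lam**2)[None, :] + np.outer(z0, lam)
        w = np.sqrt(rng.chisquare(df, size=n_draws) / df)
        self.max_abs = np.sort(np.abs(t / w[:, None]).max(axis=1))

    def adjusted_p(self, t: np.ndarray) -> np.ndarray:
        """P(max_i |T_i| >= |t|), vectorised over observed statistics."""
        t = np.abs(np.asarray(t, float))
        n = self.max_abs.size
        below = np.searchsorted(self.max_abs, t, side="left")
        return (n - below) / n


def dunnett_vs_control(
    groups: GroupSamples,
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
    null: DunnettNull | None = None,
) -> pd.DataFrame:
    """Two-sided Dunnett many-to-one comparisons against ``control``.

    Pooled-variance t statistics with N - k degrees of freedom; the
    family-wise adjusted p-value is evaluated on the equicorrelated
    multivariate-t null by seeded Monte-Carlo integration.  Returns a
    DataFrame indexed by treatment label with columns t, p_adj, sign.
    """
    if control not in groups.labels:
        raise ValueError(f"control group {control!r} missing")
    ci = groups.labels.index(control)
    treat = [i for i in range(groups.k) if i != ci]
    n = groups.n()
    means = groups.means()
    ss = sum(((v - v.mean()) ** 2).sum() for v in groups.values)
    df = int(n.sum()) - groups.k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sp = np.sqrt(ss / df)
    t_stats = np.array([
        (means[i] - means[ci]) / (sp * np.sqrt(1.0 / n[i] + 1.0 / n[ci]))
        if sp > 0 else (0.0 if means[i] == means[ci] else np.inf * np.sign(means[i] - means[ci]))
        for i in treat
    ])
    if null is None:
        null = DunnettNull(n[treat].astype(float), int(n[ci]), df, n_draws, seed)
    p_adj = null.adjusted_p(t_stats)
    return pd.DataFrame(
        {"t": t_stats, "p_adj": p_adj, "sign": np.sign(t_stats)},
        index=[groups.labels[i] for i in treat],
    )


def dunnett_matrix(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene Dunnett comparisons, sharing one Monte-Carlo null across
    genes (group sizes are common to all genes).

    Returns (p_adj, sign) DataFrames indexed by gene, one column per
    treatment class."""
    labels = np.asarray(labels)
    levs = [str(x) for x in dict.fromkeys(labels)]
    if control not in levs:
        raise ValueError(f"control group {control!r} missing")
    treat = [c for c in levs if c != control]
    masks = {c: labels == c for c in levs}
    n = {c: int(masks[c].sum()) for c in levs}
    df = matrix.n_samples - len(levs)
    null = DunnettNull(
        np.array([n[c] for c in treat], float), n[control], df, n_draws, seed
    )
    x = matrix.values
    means = {c: x[:, masks[c]].mean(axis=1) for c in levs}
    ss = np.zeros(matrix.n_genes)
    for c in levs:
        xc = x[:, masks[c]]
        ss += ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sp = np.sqrt(ss / df)
    p_cols, s_cols = {}, {}
    for c in treat:
        denom = sp * np.sqrt(1.0 / n[c] + 1.0 / n[control])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (means[c] - means[control]) / denom
        t = np.where(denom > 0, t, 0.0)
        p_cols[c] = null.adjusted_p(t)
        s_cols[c] = np.sign(means[c] - means[control])
    p = pd.DataFrame(p_cols, index=matrix.gene_ids)
    sign = pd.DataFrame(s_cols, index=matrix.gene_ids)
    return p, sign


# ---------------------------------------------------------------------------
# Games–Howell pairwise post-hoc
# ---------------------------------------------------------------------------

#: batch size above which the studentized-range tail switches to spline
#: interpolation on a grid of exact values (per-point quadrature in scipy
#: costs several ms; genome-scale calls need thousands of evaluations)
_SR_EXACT_LIMIT = 2000


def studentized_range_sf(q: np.ndarray, k: int, df: np.ndarray) -> np.ndarray:
    """Upper tail of the studentized-range distribution, batched.

    Small batches are evaluated exactly; large batches interpolate a
    bicubic spline over a (q, 1/df) grid of exact values, accurate to
    ~1e-5 on the p scale (validated against the exact evaluation in the
    test suite).
    """
    q = np.asarray(q, float)
    df = np.broadcast_to(np.asarray(df, float), q.shape)
    out = np.ones_like(q)
    ok = np.isfinite(q) & np.isfinite(df) & (df > 1)
    if not ok.any():
        return out
    qs, dfs = q[ok], df[ok]
    if qs.size <= _SR_EXACT_LIMIT:
        vals = sps.studentized_range.sf(qs, k, dfs)
    else:
        from scipy.interpolate import RectBivariateSpline

        q_hi = min(qs.max(), 40.0)
        q_grid = np.linspace(0.0, q_hi + 1e-9, 72)
        inv_lo, inv_hi = 1.0 / dfs.max(), 1.0 / max(dfs.min(), 2.0)
        inv_grid = np.linspace(inv_lo * 0.999, inv_hi * 1.001, 22)
        exact = np.empty((q_grid.size, inv_grid.size))
        for j, inv in enumerate(inv_grid):
            exact[:, j] = sps.studentized_range.sf(q_grid, k, 1.0 / inv)
        spline = RectBivariateSpline(q_grid, inv_grid, exact, kx=3, ky=3)
        vals = spline.ev(np.minimum(qs, q_hi), np.clip(1.0 / dfs, inv_grid[0], inv_grid[-1]))
        vals[qs > q_hi] = 0.0
    out[ok] = np.clip(vals, 0.0, 1.0)
    return out


def _games_howell_pair(
    m1: float, v1: float, n1: int, m2: float, v2: float, n2: int, k: int
) -> tuple[float, float, float]:
    """(t, df, p) for one unordered pair under the Games–Howell procedure."""
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return np.inf, float(n1 + n2 - 2), 0.0
    t = abs(m1 - m2) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1)
    )
    p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
    return float(t), float(df), min(max(p, 0.0), 1.0)


def games_howell_pairwise(groups: GroupSamples, alpha: float = 0.05) -> pd.DataFrame:
    """All unordered pairwise comparisons for one gene.

    For pair (i, j): t = |mean_i - mean_j| / sqrt(v_i/n_i + v_j/n_j) with
    Welch–Satterthwaite degrees of freedom; the adjusted p-value is
    P(Q_{k, df} >= t * sqrt(2)) under the studentized-range distribution
    for the full group count k.  Returns a DataFrame indexed by
    ``pair_key`` with columns t, df, p_adj, sign (sign of the mean
    difference, first-alphabetical label minus second).
    """
    k = groups.k
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = groups.n()
    if np.any(n < 2):
        raise ValueError("each group needs >= 2 observations")
    means, var = groups.means(), groups.variances()
    rows = {}
    for i, j in itertools.combinations(range(k), 2):
        t, df, p = _games_howell_pair(means[i], var[i], int(n[i]),
                                      means[j], var[j], int(n[j]), k)
        a, b = sorted((groups.labels[i], groups.labels[j]))
        first = groups.labels.index(a)
        second = groups.labels.index(b)
        rows[pair_key(a, b)] = {
            "t": t, "df": df, "p_adj": p,
            "sign": float(np.sign(means[first] - means[second])),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def games_howell_matrix(
    matrix: ExpressionMatrix, labels: np.ndarray, alpha: float = 0.05
) -> PairwiseSignificance:
    """Games–Howell post-hoc comparisons for every gene.

    Vectorised over genes per pair; the studentized-range tail is
    evaluated at the Welch degrees of freedom of each gene."""
    labels = np.asarray(labels)
    levs = sorted(str(x) for x in np.unique(labels))
    k = len(levs)
    masks = {c: labels == c for c in levs}
    n = {c: int(masks[c].sum()) for c in levs}
    if min(n.values()) < 2:
        raise ValueError("each group needs >= 2 observations")
    x = matrix.values
    means = {c: x[:, masks[c]].mean(axis=1) for c in levs}
    var = {c: x[:, masks[c]].var(axis=1, ddof=1) for c in levs}
    pairs = list(itertools.combinations(levs, 2))
    n_genes = matrix.n_genes
    q_all = np.full((len(pairs), n_genes), np.nan)
    df_all = np.full((len(pairs), n_genes), np.nan)
    diff_all = np.empty((len(pairs), n_genes))
    for i, (a, b) in enumerate(pairs):
        se2 = var[a] / n[a] + var[b] / n[b]
        diff = means[a] - means[b]
        ok = se2 > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            q_all[i, ok] = np.abs(diff[ok]) / np.sqrt(se2[ok]) * np.sqrt(2.0)
            df_all[i, ok] = se2[ok] ** 2 / (
                (var[a][ok] / n[a]) ** 2 / (n[a] - 1)
                + (var[b][ok] / n[b]) ** 2 / (n[b] - 1)
            )
        diff_all[i] = diff
    p_all = studentized_range_sf(q_all.ravel(), k, df_all.ravel()).reshape(q_all.shape)
    p_cols, s_cols = {}, {}
    for i, (a, b) in enumerate(pairs):
        p = p_all[i].copy()
        degenerate = ~np.isfinite(q_all[i])
        p[degenerate & (diff_all[i] != 0)] = 0.0
        p[degenerate & (diff_all[i] == 0)] = 1.0
        p_cols[pair_key(a, b)] = p
        s_cols[pair_key(a, b)] = np.sign(diff_all[i])
    return PairwiseSignificance(
        p=pd.DataFrame(p_cols, index=matrix.gene_ids),
        sign=pd.DataFrame(s_cols, index=matrix.gene_ids),
        classes=levs,
        alpha=alpha,
    )
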