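import itertools

import numpy as np
import pytest
from scipy import stats as sps

from celest.core_io import ExpressionMatrix
from celest.stats import (
    DunnettNull,
    GroupSamples,
    anova_gate,
    assumption_checks,
    dunnett_matrix,
    dunnett_vs_control,
    games_howell_matrix,
    games_howell_pairwise,
    kruskal_wallis_gate,
    oneway_anova_pvalues,
    route_analysis,
)


def _matrix(values):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


def _groups(rng, sizes, means=None, sds=None, df=None):
    means = means or [0.0] * len(sizes)
    sds = sds or [1.0] * len(sizes)
    vals = []
    for n, m, s in zip(sizes, means, sds):
        if df is None:
            vals.append(rng.normal(m, s, n))
        else:
            vals.append(m + s * rng.standard_t(df, n) / np.sqrt(df / (df - 2)))
    return GroupSamples(labels=[f"G{i}" for i in range(len(sizes))], values=vals)


class TestAssumptionChecks:
    def test_null_pass_rate_matches_expectation(self, rng):
        k, reps, alpha = 3, 400, 0.05
        passed = 0
        for _ in range(reps):
            g = _groups(rng, [25] * k)
            checks = assumption_checks(g, alpha)
            passed += checks["normal"] and checks["homoscedastic"]
        expected = (1 - alpha) ** (k + 1)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(passed / reps - expected) < 4 * se

    def test_heavy_tails_flagged_non_normal(self, rng):
        g = _groups(rng, [300, 300], df=3)
        assert assumption_checks(g)["normal"] is False

    def test_tiny_group_counts_as_non_normal(self, rng):
        g = GroupSamples(labels=["a", "b"],
                         values=[rng.normal(size=2), rng.normal(size=30)])
        assert assumption_checks(g)["normal"] is False

    def test_unequal_variances_flagged(self, rng):
        g = _groups(rng, [80, 80], sds=[1.0, 4.0])
        assert assumption_checks(g)["homoscedastic"] is False


class TestAnovaGate:
    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=(50, 24))
        labels = np.repeat(["a", "b"], 12)
        p_f = oneway_anova_pvalues(x, labels)
        for i in range(50):
            t = sps.ttest_ind(x[i, :12], x[i, 12:], equal_var=True)
            assert p_f[i] == pytest.approx(t.pvalue, abs=1e-10)

    def test_null_retention_near_alpha(self, rng):
        x = rng.normal(size=(3000, 40))
        labels = np.repeat(["a", "b", "c", "d"], 10)
        kept, _ = anova_gate(_matrix(x), labels, alpha=0.05)
        frac = len(kept) / 3000
        se = np.sqrt(0.05 * 0.95 / 3000)
        assert abs(frac - 0.05) < 3 * se

    def test_power_matches_noncentral_f(self, rng):
        k, n, shift, sd, alpha = 3, 20, 0.8, 1.0, 0.05
        reps = 2000
        x = rng.normal(size=(reps, k * n))
        x[:, :n] += shift
        labels = np.repeat(["a", "b", "c"], n)
        p = oneway_anova_pvalues(x, labels)
        power_mc = (p < alpha).mean()
        means = np.array([shift, 0, 0])
        lam = n * ((means - means.mean()) ** 2).sum() / sd**2
        fcrit = sps.f.isf(alpha, k - 1, k * n - k)
        power_exact = sps.ncf.sf(fcrit, k - 1, k * n - k, lam)
        se = np.sqrt(power_exact * (1 - power_exact) / reps)
        assert abs(power_mc - power_exact) < 3.5 * se

    def test_matches_scipy_f_oneway(self, rng):
        x = rng.normal(size=(10, 30))
        labels = np.repeat(["a", "b", "c"], 10)
        p = oneway_anova_pvalues(x, labels)
        for i in range(10):
            ref = sps.f_oneway(x[i, :10], x[i, 10:20], x[i, 20:]).pvalue
            assert p[i] == pytest.approx(ref, abs=1e-12)


class TestKruskalWallisGate:
    def test_two_groups_matches_mann_whitney_asymptotic(self, rng):
        x = rng.normal(size=(40, 30))
        labels = np.repeat(["a", "b"], 15)
        _, p = kruskal_wallis_gate(_matrix(x), labels)
        for i in range(40):
            mw = sps.mannwhitneyu(x[i, :15], x[i, 15:], alternative="two-sided",
                                  method="asymptotic", use_continuity=False)
            assert p.iloc[i] == pytest.approx(mw.pvalue, abs=1e-9)

    def test_null_retention_near_alpha(self, rng):
        x = rng.normal(size=(2000, 36))
        labels = np.repeat(["a", "b", "c"], 12)
        kept, _ = kruskal_wallis_gate(_matrix(x), labels, alpha=0.05)
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(len(kept) / 2000 - 0.05) < 3 * se

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=(30, 24))
        labels = np.repeat(["a", "b", "c"], 8)
        _, p1 = kruskal_wallis_gate(_matrix(x), labels)
        _, p2 = kruskal_wallis_gate(_matrix(np.expm1(x) + x**3 / 3 + x), labels)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self, rng):
        g = _groups(rng, [15, 12], means=[0.6, 0.0])
        res = dunnett_vs_control(g, control="G1", n_draws=400_000, seed=0)
        t = sps.ttest_ind(g.values[0], g.values[1], equal_var=True)
        assert res.loc["G0", "p_adj"] == pytest.approx(t.pvalue, abs=5e-3)

    def test_adjusted_p_at_least_unadjusted(self, rng):
        g = _groups(rng, [12, 12, 12, 12], means=[0.5, -0.3, 0.1, 0.0])
        res = dunnett_vs_control(g, control="G3", seed=0)
        df = sum(v.size for v in g.values) - 4
        for lbl in res.index:
            raw = 2 * sps.t.sf(abs(res.loc[lbl, "t"]), df)
            assert res.loc[lbl, "p_adj"] >= raw - 5e-3

    def test_agrees_with_scipy_dunnett(self, rng):
        samples = [rng.normal(0.8, 1, 14), rng.normal(-0.4, 1, 10), rng.normal(0, 1, 12)]
        control = rng.normal(0, 1, 16)
        ref = sps.dunnett(*samples, control=control,
                          random_state=np.random.default_rng(5))
        g = GroupSamples(labels=["a", "b", "c", "ctrl"],
                         values=samples + [control])
        res = dunnett_vs_control(g, control="ctrl", n_draws=400_000, seed=1)
        np.testing.assert_allclose(
            res.loc[["a", "b", "c"], "p_adj"].to_numpy(), ref.pvalue, atol=7e-3)

    def test_null_familywise_error_near_alpha(self, rng):
        n_fam, k, n = 2000, 5, 12
        x = rng.normal(size=(n_fam, (k + 1) * n))
        labels = np.repeat([f"t{i}" for i in range(k)] + ["ctrl"], n)
        p, _ = dunnett_matrix(_matrix(x), labels, control="ctrl", seed=3)
        fwer = (p.min(axis=1) < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_fam)
        assert abs(fwer - 0.05) < 3.5 * se

    def test_missing_control_rejected(self, rng):
        g = _groups(rng, [10, 10])
        with pytest.raises(ValueError, match="control"):
            dunnett_vs_control(g, control="nope")


class TestGamesHowell:
    def test_two_groups_reduces_to_welch_t(self, rng):
        for _ in range(5):
            g = _groups(rng, [14, 9], means=[0.7, 0.0], sds=[1.0, 2.5])
            res = games_howell_pairwise(g)
            welch = sps.ttest_ind(g.values[0], g.values[1], equal_var=False)
            assert res["p_adj"].iloc[0] == pytest.approx(welch.pvalue, abs=1e-6)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        sizes = [12, 18, 9, 15]
        g = _groups(rng, sizes, means=[0, 0.5, 1.0, 0], sds=[1, 2, 1, 3])
        res = games_howell_pairwise(g)
        df = pd.DataFrame({
            "y": np.concatenate(g.values),
            "grp": np.repeat(g.labels, sizes),
        })
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="grp")
        for _, row in ref.iterrows():
            key = "|".join(sorted((row["A"], row["B"])))
            assert res.loc[key, "p_adj"] == pytest.approx(row["pval"], abs=1e-6)

    def test_matches_permutation_max_t_oracle(self):
        """On a balanced equal-variance fixture the studentized-range
        adjustment approximates the permutation distribution of the
        maximum pairwise |t|."""
        rng = np.random.default_rng(77)
        sizes = [5, 5, 5]
        g = _groups(rng, sizes, means=[0.0, 1.2, 0.4])
        res = games_howell_pairwise(g)
        pooled = np.concatenate(g.values)
        n_perm = 20_000
        obs_t = {}
        for (i, a), (j, b) in itertools.combinations(enumerate(g.labels), 2):
            t = sps.ttest_ind(g.values[i], g.values[j], equal_var=False)
            obs_t["|".join(sorted((a, b)))] = abs(t.statistic)
        max_ts = np.empty(n_perm)
        prng = np.random.default_rng(88)
        for r in range(n_perm):
            perm = prng.permutation(pooled)
            parts = [perm[:5], perm[5:10], perm[10:]]
            ts = [abs(sps.ttest_ind(pa, pb, equal_var=False).statistic)
                  for pa, pb in itertools.combinations(parts, 2)]
            max_ts[r] = max(ts)
        for key, t in obs_t.items():
            p_perm = (max_ts >= t).mean()
            assert res.loc[key, "p_adj"] == pytest.approx(p_perm, abs=0.06)

    def test_zero_variance_equal_means_p_one(self):
        g = GroupSamples(labels=["a", "b"],
                         values=[np.full(5, 2.0), np.full(6, 2.0)])
        res = games_howell_pairwise(g)
        assert res["p_adj"].iloc[0] == 1.0

    def test_matrix_and_single_gene_paths_agree(self, rng):
        x = rng.normal(size=(12, 30))
        labels = np.repeat(["a", "b", "c"], 10)
        pw = games_howell_matrix(_matrix(x), labels)
        for i in range(12):
            g = GroupSamples.from_labels(x[i], labels)
            single = games_howell_pairwise(g)
            for key in single.index:
                assert pw.p.iloc[i][key] == pytest.approx(
                    single.loc[key, "p_adj"], abs=1e-10)

    def test_decisions_monotone_in_alpha(self, rng):
        x = rng.normal(size=(40, 30))
        labels = np.repeat(["a", "b", "c"], 10)
        pw = games_howell_matrix(_matrix(x), labels, alpha=0.05)
        strict = pw.p < 0.01
        loose = pw.p < 0.10
        assert (strict.to_numpy() <= loose.to_numpy()).all()


def test_batched_studentized_range_matches_exact():
    """The spline-interpolated tail used for genome-scale batches agrees
    with scipy's exact evaluation well below any decision tolerance."""
    from celest.stats import studentized_range_sf

    rng = np.random.default_rng(3)
    q = rng.uniform(0.2, 8.0, 5000)
    df = rng.uniform(4, 90, 5000)
    batched = studentized_range_sf(q, 5, df)
    idx = rng.choice(5000, 25, replace=False)
    exact = sps.studentized_range.sf(q[idx], 5, df[idx])
    np.testing.assert_allclose(batched[idx], exact, atol=1e-4)


class TestRouting:
    def test_gaussian_data_routes_parametric(self, rng):
        x = rng.normal(size=(150, 60))
        labels = np.repeat(["a", "b", "c"], 20)
        assert route_analysis(_matrix(x), labels, seed=0) == "parametric"

    def test_heavy_tailed_data_routes_nonparametric(self, rng):
        x = rng.standard_t(2, size=(150, 90))
        labels = np.repeat(["a", "b", "c"], 30)
        assert route_analysis(_matrix(x), labels, seed=0) == "nonparametric"

    def test_routing_deterministic(self, rng):
        x = rng.normal(size=(400, 45))
        labels = np.repeat(["a", "b", "c"], 15)
        r1 = route_analysis(_matrix(x), labels, seed=4)
        r2 = route_analysis(_matrix(x), labels, seed=4)
        assert r1 == r2
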