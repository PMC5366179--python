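import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from celest.markers import (
    BiomarkerReport,
    case_control_degs,
    ce_deg_sets,
    dice_coefficient,
    dice_confidence_interval,
    fisher_enrichment,
    select_biomarkers,
)
from celest.stats import PairwiseSignificance, pair_key


def _pairwise(p_by_gene: dict[str, dict[str, float]], classes, alpha=0.05):
    """Build a PairwiseSignificance from {gene: {pair: p}} with p=1 default."""
    cols = [pair_key(a, b) for a, b in itertools.combinations(sorted(classes), 2)]
    genes = list(p_by_gene)
    p = pd.DataFrame(1.0, index=genes, columns=cols)
    for g, d in p_by_gene.items():
        for key, val in d.items():
            p.loc[g, key] = val
    sign = pd.DataFrame(1.0, index=genes, columns=cols)
    return PairwiseSignificance(p=p, sign=sign, classes=sorted(classes), alpha=alpha)


class TestCeDegAndBiomarkers:
    def test_gene_significant_everywhere_in_every_set(self):
        classes = ["A", "B", "C"]
        pw = _pairwise({"g1": {k: 0.001 for k in ["A|B", "A|C", "B|C"]}}, classes)
        ce = ce_deg_sets(pw)
        assert all(ce[c] == {"g1"} for c in classes)

    def test_gene_significant_only_for_pairs_of_one_class(self):
        classes = ["A", "B", "C"]
        pw = _pairwise({"g1": {"A|B": 0.001, "A|C": 0.001}}, classes)
        ce = ce_deg_sets(pw)
        assert ce["A"] == {"g1"}
        assert ce["B"] == set() and ce["C"] == set()

    def test_single_class_gene_selected_as_biomarker(self):
        classes = ["A", "B", "C"]
        pw = _pairwise({"g1": {"A|B": 0.001, "A|C": 0.001}}, classes)
        report = select_biomarkers(pw)
        assert report.biomarkers["A"] == {"g1"}
        assert report.biomarkers["B"] == set()

    def test_ce_deg_with_extra_pair_excluded_from_biomarkers(self):
        classes = ["A", "B", "C"]
        pw = _pairwise(
            {"g1": {"A|B": 0.001, "A|C": 0.001, "B|C": 0.01}}, classes
        )
        report = select_biomarkers(pw)
        assert "g1" in report.ce_degs["A"]
        assert report.biomarkers["A"] == set()

    def test_two_class_gene_never_a_biomarker(self):
        classes = ["A", "B", "C", "D"]
        pairs = {k: 0.001 for k in ["A|B", "A|C", "A|D", "B|C", "B|D"]}
        pw = _pairwise({"g1": pairs}, classes)
        report = select_biomarkers(pw)
        assert "g1" in report.ce_degs["A"] and "g1" in report.ce_degs["B"]
        assert all(not s for s in report.biomarkers.values())

    def test_missing_pair_rejected(self):
        classes = ["A", "B", "C"]
        pw = _pairwise({"g1": {}}, classes)
        pw.p = pw.p.drop(columns=["B|C"])
        with pytest.raises(ValueError, match="missing"):
            select_biomarkers(pw)

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError, match="not within"):
            BiomarkerReport(ce_degs={"A": set()}, biomarkers={"A": {"g"}})
        with pytest.raises(ValueError, match="overlap"):
            BiomarkerReport(
                ce_degs={"A": {"g"}, "B": {"g"}},
                biomarkers={"A": {"g"}, "B": {"g"}},
            )


class TestCaseControlDegs:
    def test_planted_shift_lands_in_one_class_only(self, rng):
        from celest.core_io import ExpressionMatrix

        n = 20
        labels = np.repeat(["ALL", "AML", "CTR"], n)
        x = rng.normal(size=(30, 3 * n))
        x[0, :n] += 3.0  # strong up-shift in ALL only
        m = ExpressionMatrix(x, [f"g{i}" for i in range(30)],
                             [f"s{j}" for j in range(3 * n)])
        degs = case_control_degs(m, labels, control="CTR", seed=0)
        assert "g0" in degs["ALL"].up
        assert "g0" not in degs["AML"].genes

    def test_null_set_sizes_near_alpha(self, rng):
        from celest.core_io import ExpressionMatrix

        g, n = 3000, 15
        labels = np.repeat(["A", "B", "CTR"], n)
        x = rng.normal(size=(g, 3 * n))
        m = ExpressionMatrix(x, [f"g{i}" for i in range(g)],
                             [f"s{j}" for j in range(3 * n)])
        degs = case_control_degs(m, labels, control="CTR", alpha=0.05, seed=1)
        for c in ("A", "B"):
            frac = len(degs[c].genes) / g
            # Dunnett familywise alpha splits across the two comparisons
            assert frac < 0.05
            assert frac > 0.005

    def test_up_down_partition_sums(self, rng):
        from celest.core_io import ExpressionMatrix

        x = rng.normal(size=(200, 30))
        x[:50, :10] += 1.5
        labels = np.repeat(["A", "B", "CTR"], 10)
        m = ExpressionMatrix(x, [f"g{i}" for i in range(200)],
                             [f"s{j}" for j in range(30)])
        degs = case_control_degs(m, labels, control="CTR", seed=2)
        for d in degs.values():
            counts = d.counts
            assert counts["up"] + counts["down"] == counts["total"]
            assert not (d.up & d.down)

    def test_missing_control_rejected(self, rng):
        from celest.core_io import ExpressionMatrix

        m = ExpressionMatrix(rng.normal(size=(5, 10)),
                             [f"g{i}" for i in range(5)],
                             [f"s{j}" for j in range(10)])
        with pytest.raises(ValueError, match="control"):
            case_control_degs(m, np.repeat(["A", "B"], 5), control="CTR")


class TestDice:
    def test_identical_sets_give_one(self):
        assert dice_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert dice_coefficient({"a"}, {"b"}) == 0.0

    def test_both_empty_convention(self):
        assert dice_coefficient(set(), set()) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_count_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(300)]
        a = set(rng.choice(universe, size=120, replace=False))
        b = set(rng.choice(universe, size=80, replace=False))
        inter = sum(1 for g in universe if g in a and g in b)
        assert dice_coefficient(a, b) == pytest.approx(
            2 * inter / (len(a) + len(b)), abs=1e-12)

    def test_dice_jaccard_identity(self, rng):
        universe = [f"g{i}" for i in range(200)]
        a = set(rng.choice(universe, 90, replace=False))
        b = set(rng.choice(universe, 60, replace=False))
        j = len(a & b) / len(a | b)
        assert dice_coefficient(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_ci_identical_sets_degenerate(self):
        u = {f"g{i}" for i in range(50)}
        a = {f"g{i}" for i in range(20)}
        lo, hi = dice_confidence_interval(a, a, u, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_ci_contains_point_estimate(self, rng):
        hits = 0
        reps = 30
        for s in range(reps):
            prng = np.random.default_rng(s)
            u = [f"g{i}" for i in range(150)]
            a = set(prng.choice(u, 60, replace=False))
            b = set(prng.choice(u, 70, replace=False))
            d = dice_coefficient(a, b)
            lo, hi = dice_confidence_interval(a, b, set(u), n_boot=500, seed=s)
            hits += lo <= d <= hi
        assert hits >= reps - 1

    def test_ci_narrows_with_universe_size(self):
        widths = []
        for scale in (100, 1600):
            u = [f"g{i}" for i in range(scale)]
            a = set(u[: scale // 2])
            b = set(u[scale // 4: 3 * scale // 4])
            lo, hi = dice_confidence_interval(a, b, set(u), n_boot=500, seed=3)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_deterministic_given_seed(self):
        u = {f"g{i}" for i in range(80)}
        a = {f"g{i}" for i in range(30)}
        b = {f"g{i}" for i in range(20, 50)}
        ci1 = dice_confidence_interval(a, b, u, seed=9)
        ci2 = dice_confidence_interval(a, b, u, seed=9)
        assert ci1 == ci2


class TestFisherEnrichment:
    def test_perfect_split_extreme(self):
        universe = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(20)}
        res = fisher_enrichment(query, universe, {"term": set(query)})
        assert res["p"].iloc[0] < 1e-8
        assert res["or_infinite"].iloc[0]

    def test_small_table_matches_hand_enumeration(self):
        # table [[3,1],[1,3]]: universe 8, query 4, term 4, overlap 3
        universe = {f"g{i}" for i in range(8)}
        query = {"g0", "g1", "g2", "g3"}
        term = {"g0", "g1", "g2", "g4"}
        res = fisher_enrichment(query, universe, {"t": term})
        # two-sided p = sum of hypergeometric probabilities <= P(X=3)
        probs = [hypergeom.pmf(x, 8, 4, 4) for x in range(5)]
        p_obs = probs[3]
        expected = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_null_p_uniform(self, rng):
        universe = [f"g{i}" for i in range(400)]
        terms = {}
        for t in range(150):
            prng = np.random.default_rng(1000 + t)
            terms[f"t{t}"] = set(prng.choice(universe, 50, replace=False))
        query = set(rng.choice(universe, 100, replace=False))
        res = fisher_enrichment(query, set(universe), terms)
        # discrete p-values are conservative; KS against uniform at 1%
        assert kstest(res["p"], "uniform").pvalue > 0.01 or res["p"].mean() > 0.45

    def test_disjoint_term_skipped_with_warning(self):
        universe = {"g1", "g2"}
        with pytest.warns(UserWarning, match="does not intersect"):
            res = fisher_enrichment({"g1"}, universe, {"far": {"x"}})
        assert res.empty

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"q"}, {"g"}, {})
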