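import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import kstest

from icbscreen import stats as ast
from icbscreen.io import ExpressionMatrix, GeneSet
from icbscreen.simulate import CohortTruth, simulate_clinical, simulate_variants
from icbscreen.features import compute_tmb


def bh_oracle(p):
    """Step-up definition computed directly: q_i = min over j>=rank(i) of
    m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBH:
    @given(
        hst.lists(hst.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=10)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(ast.bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_closed_form_example(self):
        np.testing.assert_allclose(
            ast.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )


class TestExpressionFilter:
    @staticmethod
    def expr_with_fraction(frac, n=100):
        values = np.zeros((1, n))
        values[0, : int(round(frac * n))] = 1.0  # >= 0.5 in frac of samples
        return ExpressionMatrix(["G0"], [f"S{j}" for j in range(n)], values)

    def test_below_30pct_dropped(self):
        expr = self.expr_with_fraction(0.29)
        assert ast.expression_filter(expr, {"G0"}) == []

    def test_exactly_30pct_kept(self):
        expr = self.expr_with_fraction(0.30)
        assert ast.expression_filter(expr, {"G0"}) == ["G0"]

    def test_noncoding_dropped_and_empty_list_rejected(self):
        expr = self.expr_with_fraction(1.0)
        assert ast.expression_filter(expr, {"OTHER"}) == []
        with pytest.raises(ValueError):
            ast.expression_filter(expr, set())


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 5, size=(10, 5))
        expr = ExpressionMatrix(
            [f"G{i}" for i in range(10)],
            [f"S{j}" for j in range(10)],
            np.hstack([vals, vals]),
        )
        response = pd.Series([1] * 5 + [0] * 5, index=expr.sample_ids)
        de = ast.differential_expression(expr, response)
        np.testing.assert_allclose(de["lfc"], 0.0, atol=1e-12)
        assert (de["p"] > 0.99).all()

    def test_shifted_gene_detected(self, two_group_expr):
        expr, response = two_group_expr
        de = ast.differential_expression(expr, response)
        assert de.loc["G0", "p"] < 1e-6
        assert de.loc["G0", "lfc"] == pytest.approx(2.0, abs=0.2)

    def test_global_null_p_uniform(self):
        rng = np.random.default_rng(1)
        expr = ExpressionMatrix(
            [f"G{i}" for i in range(300)],
            [f"S{j}" for j in range(40)],
            rng.normal(4, 1, size=(300, 40)).clip(0),
        )
        response = pd.Series([1] * 20 + [0] * 20, index=expr.sample_ids)
        de = ast.differential_expression(expr, response)
        assert kstest(de["p"], "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        rng = np.random.default_rng(2)
        expr = ExpressionMatrix(
            ["G0"], [f"S{j}" for j in range(5)], rng.uniform(1, 2, (1, 5))
        )
        response = pd.Series([1, 1, 0, 0, 0], index=expr.sample_ids)
        with pytest.raises(ValueError, match="3 samples"):
            ast.differential_expression(expr, response)


class TestPrevalenceFilter:
    def test_rules(self):
        n = 100
        feats = pd.DataFrame(
            {
                "rare": [1] * 4 + [0] * (n - 4),
                "edge": [1] * 5 + [0] * (n - 5),
                "cont": np.linspace(0, 1, n),
            }
        )
        kinds = {"rare": "binary", "edge": "binary", "cont": "continuous"}
        out = ast.prevalence_filter(feats, kinds)
        assert list(out.columns) == ["edge", "cont"]


class TestLogisticScreen:
    def test_binary_or_matches_cross_product_oracle(self):
        # feature x response layout a=10, b=5, c=5, d=10
        x = [1] * 15 + [0] * 15
        y = [1] * 10 + [0] * 5 + [1] * 5 + [0] * 10
        feats = pd.DataFrame({"f": x}, index=[f"S{i}" for i in range(30)])
        resp = pd.Series(y, index=feats.index)
        res = ast.logistic_screen(feats, resp)
        assert res.loc["f", "odds_ratio"] == pytest.approx(4.0, abs=1e-6)
        assert res.loc["f", "ci_low"] < 4.0 < res.loc["f", "ci_high"]

    def test_null_feature_or_near_one(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            x = rng.normal(size=120)
            y = rng.integers(0, 2, size=120)
            feats = pd.DataFrame({"f": x}, index=[f"S{i}" for i in range(120)])
            res = ast.logistic_screen(feats, pd.Series(y, index=feats.index))
            if res.loc["f", "p"] > 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep * 0.9  # >= 90% non-significant with slack

    def test_separated_feature_flagged_and_excluded_from_bh(self):
        y = [1] * 10 + [0] * 10
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(
            {
                "sep": y,  # perfectly separates
                "ok": rng.normal(size=20),
            },
            index=[f"S{i}" for i in range(20)],
        )
        res = ast.logistic_screen(feats, pd.Series(y, index=feats.index))
        assert bool(res.loc["sep", "separated"])
        assert np.isnan(res.loc["sep", "q"])
        assert res.loc["ok", "q"] == pytest.approx(res.loc["ok", "p"])  # m == 1

    def test_tiers_follow_thresholds(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(size=n)
        logit = 2.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        feats = pd.DataFrame(
            {"strong": x, "noise": rng.normal(size=n)},
            index=[f"S{i}" for i in range(n)],
        )
        res = ast.logistic_screen(feats, pd.Series(y, index=feats.index))
        assert res.loc["strong", "tier"] == "significant"

    def test_tmb_recovery_under_generative_model(self):
        """With a strong TMB effect on response, TMB ranks among the top 3
        screened features by q in >= 9/10 seeded replicates."""
        wins = 0
        for rep in range(10):
            variants = simulate_variants(150, seed=100 + rep)
            tmb = compute_tmb(variants, 33.0)
            rng = np.random.default_rng(200 + rep)
            feats = pd.DataFrame(
                {"log_tmb": tmb["log_tmb"] - tmb["log_tmb"].mean()},
                index=tmb.index,
            )
            for j in range(7):
                feats[f"noise_{j}"] = rng.normal(size=len(feats))
            truth = CohortTruth(list(feats.index))
            truth.features = feats
            clin = simulate_clinical(
                truth, {"log_tmb": 1.0}, intercept=-0.5, seed=300 + rep
            )
            res = ast.logistic_screen(
                feats, clin.set_index("sample_id")["response"]
            )
            top3 = res.sort_values("q").head(3).index
            wins += int("log_tmb" in top3)
        assert wins >= 9


class TestHypergeometricORA:
    def test_exact_small_case(self):
        universe = [f"g{i}" for i in range(10)]
        query = GeneSet("q", tuple(universe[:5]))
        ref = GeneSet("r", tuple(universe[:5]))
        out = ast.hypergeometric_ora(query, [ref], universe)
        assert out.loc["r", "p"] == pytest.approx(1 / math.comb(10, 5), rel=1e-9)

    def test_no_overlap_near_one(self):
        universe = [f"g{i}" for i in range(10)]
        query = GeneSet("q", tuple(universe[:3]))
        ref = GeneSet("r", tuple(universe[7:]))
        out = ast.hypergeometric_ora(query, [ref], universe)
        assert out.loc["r", "p"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle(self):
        """Upper-tail p equals exhaustive enumeration over all query draws
        for universes up to 12 genes."""
        rng = np.random.default_rng(5)
        for M, n_ref, n_query in [(8, 3, 4), (10, 5, 5), (12, 6, 3)]:
            universe = [f"g{i}" for i in range(M)]
            ref_genes = set(rng.choice(universe, size=n_ref, replace=False))
            query_genes = tuple(rng.choice(universe, size=n_query, replace=False))
            k_obs = len(ref_genes & set(query_genes))
            total = hits = 0
            for combo in itertools.combinations(universe, n_query):
                total += 1
                hits += len(ref_genes & set(combo)) >= k_obs
            oracle = hits / total
            out = ast.hypergeometric_ora(
                GeneSet("q", query_genes), [GeneSet("r", tuple(ref_genes))], universe
            )
            assert out.loc["r", "p"] == pytest.approx(oracle, rel=1e-9)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ast.hypergeometric_ora(
                GeneSet("q", ("x",)), [GeneSet("r", ("a",))], ["a", "b"]
            )


def de_frame(scores, genes=None):
    genes = genes or [f"G{i}" for i in range(len(scores))]
    return pd.DataFrame(
        {"lfc": 1.0, "p": [10.0 ** (-s) for s in scores]}, index=genes
    )


class TestCompareSetSignificance:
    def test_fully_separated_scores_exact_p(self):
        de = de_frame([1, 2, 3, 4, 5, 6])
        a = GeneSet("a", ("G0", "G1", "G2"))
        b = GeneSet("b", ("G3", "G4", "G5"))
        out = ast.compare_set_significance(de, a, b)
        assert out["U"] == 0.0
        assert out["p"] == pytest.approx(0.1, rel=1e-9)  # 2 / C(6,3)

    def test_identical_distributions_near_one(self):
        rng = np.random.default_rng(6)
        scores = list(rng.uniform(0.5, 3, size=8))
        de = de_frame(scores + scores, genes=[f"G{i}" for i in range(16)])
        a = GeneSet("a", tuple(f"G{i}" for i in range(8)))
        b = GeneSet("b", tuple(f"G{i}" for i in range(8, 16)))
        out = ast.compare_set_significance(de, a, b)
        assert out["p"] > 0.9

    def test_matches_exhaustive_permutation(self):
        """The exact two-sided p equals the label-permutation distribution of
        U for pooled sizes up to 8."""
        rng = np.random.default_rng(7)
        scores = list(rng.uniform(0, 4, size=8))
        de = de_frame(scores)
        a_genes = ("G0", "G1", "G2", "G3")
        b_genes = ("G4", "G5", "G6", "G7")
        out = ast.compare_set_significance(
            de, GeneSet("a", a_genes), GeneSet("b", b_genes)
        )
        pooled = np.array(scores)
        obs_u = out["U"]
        n_a = 4

        def u_stat(a_idx):
            a = pooled[list(a_idx)]
            b = pooled[[i for i in range(8) if i not in set(a_idx)]]
            gt = sum((x > y) for x in a for y in b)
            ties = sum((x == y) for x in a for y in b)
            return gt + ties / 2

        us = [u_stat(c) for c in itertools.combinations(range(8), n_a)]
        us = np.array(us)
        mu = n_a * 4 / 2
        perm_p = np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-12)
        assert out["p"] == pytest.approx(perm_p, rel=1e-9)

    def test_overlap_excluded(self):
        de = de_frame([1, 2, 3, 4, 5, 6, 7])
        a = GeneSet("a", ("G0", "G1", "G2", "G3"))
        b = GeneSet("b", ("G3", "G4", "G5", "G6"))
        out = ast.compare_set_significance(de, a, b)
        assert out["n_a"] == 3 and out["n_b"] == 3


class TestBivariateModel:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(8)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        y = 2 + 3 * x1 - x2
        out = ast.bivariate_expression_model(y, x1, x2)
        assert out["r2_combined"] == pytest.approx(1.0)
        assert out["coefficients"]["x1"] == pytest.approx(3.0)

    def test_independent_noise_low_r2(self):
        rng = np.random.default_rng(9)
        out = ast.bivariate_expression_model(
            rng.normal(size=200), rng.normal(size=200), rng.normal(size=200)
        )
        assert out["r2_combined"] < 0.05

    def test_nested_model_property(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            x1, x2 = rng.normal(size=30), rng.normal(size=30)
            y = x1 + rng.normal(size=30)
            out = ast.bivariate_expression_model(y, x1, x2)
            assert out["r2_combined"] >= max(out["r2_x1"], out["r2_x2"]) - 1e-12

    def test_collinear_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            ast.bivariate_expression_model(x, x, 2 * x)


class TestBinFeature:
    def test_rules(self):
        z = pd.Series([0.3, -0.1, 0.0], index=list("abc"))
        out = ast.bin_feature(z, "zscore")
        assert list(out) == ["high", "low", "low"]
        burden = pd.Series([1.0, 2.0, 3.0, 2.0], index=list("abcd"))
        outb = ast.bin_feature(burden, "burden")
        assert list(outb) == ["low", "low", "high", "low"]  # median ties to low
        clusters = pd.Series(["M-1", "M-2", "M-1"], index=list("abc"))
        outc = ast.bin_feature(clusters, "cluster", cluster="M-1")
        assert list(outc) == ["high", "low", "high"]
        alt = pd.Series([1.0, 0.0], index=list("ab"))
        assert list(ast.bin_feature(alt, "alteration")) == ["high", "low"]
        with pytest.raises(ValueError, match="kind"):
            ast.bin_feature(z, "quantile")


def logrank_oracle(times, events, groups):
    """Textbook log-rank chi-square computed directly from risk tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == "A")).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == "A")).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestKMLogrank:
    def test_identical_groups_null(self):
        times = pd.Series([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = pd.Series([1, 1, 0, 1, 1, 1, 0, 1])
        groups = pd.Series(["high"] * 4 + ["low"] * 4)
        out = ast.km_logrank(times, events, groups)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_oracle_toy(self):
        times = pd.Series([1.0, 2.0, 3.0, 4.0])
        events = pd.Series([1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"])
        oracle = logrank_oracle(times, events, groups)
        out = ast.km_logrank(times, events, groups)
        assert out["statistic"] == pytest.approx(oracle, abs=1e-6)

    def test_power_on_separated_exponentials(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            a = rng.exponential(1.0, size=100)
            b = rng.exponential(4.0, size=100)
            times = pd.Series(np.concatenate([a, b]))
            events = pd.Series(np.ones(200, dtype=int))
            groups = pd.Series(["A"] * 100 + ["B"] * 100)
            out = ast.km_logrank(times, events, groups)
            hits += out["p"] < 1e-4
        assert hits >= 0.95 * n_rep

    def test_no_events_rejected(self):
        times = pd.Series([1.0, 2.0])
        events = pd.Series([0, 0])
        groups = pd.Series(["A", "B"])
        with pytest.raises(ValueError, match="events"):
            ast.km_logrank(times, events, groups)


class TestCrossCorrelationCluster:
    def test_duplicated_feature_same_block(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=60)
        feats = pd.DataFrame(
            {"a": f, "b": f, "c": rng.normal(size=60), "d": -f}
        )
        corr, blocks, order = ast.cross_correlation_cluster(feats, n_blocks=2)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert blocks["a"] == blocks["b"]

    def test_anticorrelated_families_separate(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=80)
        feats = pd.DataFrame(
            {
                "u1": base + rng.normal(0, 0.2, 80),
                "u2": base + rng.normal(0, 0.2, 80),
                "v1": -base + rng.normal(0, 0.2, 80),
                "v2": -base + rng.normal(0, 0.2, 80),
            }
        )
        _, blocks, _ = ast.cross_correlation_cluster(feats, n_blocks=2)
        assert blocks["u1"] == blocks["u2"]
        assert blocks["v1"] == blocks["v2"]
        assert blocks["u1"] != blocks["v1"]

    def test_symmetric_unit_diagonal_and_constant_dropped(self):
        rng = np.random.default_rng(14)
        feats = pd.DataFrame(
            {
                "a": rng.normal(size=30),
                "b": rng.normal(size=30),
                "c": rng.normal(size=30),
                "const": np.ones(30),
            }
        )
        corr, blocks, _ = ast.cross_correlation_cluster(feats, n_blocks=2)
        assert "const" not in corr.columns
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
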