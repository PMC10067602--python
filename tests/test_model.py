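import numpy as np
import pandas as pd
import pytest

from pairsurv.model import (
    lasso_select,
    multivariate_fit,
    published_model,
    score_expression,
    score_mkpc,
    train_funnel,
    univariate_screen,
)
from pairsurv.pairs import PairFeatureMatrix, encode_pairs, pair_label
from pairsurv.simulate import SimulationConfig, simulate_cohort
from oracles import newton_breslow_cox


def pfm_from_rows(rows, labels=None):
    n = len(rows[0])
    labels = labels or [f"a{i}|b{i}" for i in range(len(rows))]
    pairs = [tuple(l.split("|")) for l in labels]
    ind = pd.DataFrame(rows, index=labels, columns=[f"s{i}" for i in range(n)])
    return PairFeatureMatrix(pairs=pairs, indicators=ind)


def surv_df(time, event):
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"s{i}" for i in range(len(time))], name="sample"),
    )


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = SimulationConfig(
        n_samples=400, n_genes=20, n_signature_genes=0,
        planted_pairs=[(("G0001", "G0002"), 1.0)],
        censoring_rate_target=0.3, seed=21,
    )
    return simulate_cohort(cfg)


class TestUnivariateScreen:
    def test_matches_newton_oracle_on_distinct_times(self):
        """Single-covariate fit equals brute-force Breslow maximization to 1e-6."""
        rng = np.random.default_rng(4)
        n = 28
        x = rng.binomial(1, 0.5, n)
        time = np.round(rng.exponential(100, n) * np.exp(-0.7 * x), 6)
        assert len(set(time)) == n
        event = np.ones(n, int)
        pfm = pfm_from_rows([list(x)], ["A|B"])
        res = univariate_screen(pfm, surv_df(time, event))
        beta, se = newton_breslow_cox(x[:, None], time, event)
        assert res.loc["A|B", "coef"] == pytest.approx(beta[0], abs=1e-6)
        assert res.loc["A|B", "se"] == pytest.approx(se[0], abs=1e-6)

    def test_planted_pair_passes_with_accurate_coefficient(self, planted_cohort):
        c = planted_cohort
        pfm = encode_pairs(c.expression, [("G0001", "G0002")])
        res = univariate_screen(pfm, c.survival)
        row = res.loc["G0001|G0002"]
        assert row["passed"]
        assert abs(row["coef"] - 1.0) <= 3 * row["se"]

    def test_zero_variance_pair_skipped(self):
        pfm = pfm_from_rows([[1] * 8, [1, 0, 1, 0, 1, 0, 1, 0]])
        time = [5, 7, 9, 11, 13, 15, 17, 19.0]
        res = univariate_screen(pfm, surv_df(time, [1] * 8))
        assert not res.iloc[0]["passed"] and np.isnan(res.iloc[0]["coef"])
        assert np.isfinite(res.iloc[1]["coef"])


class TestLassoSelect:
    def test_single_strong_pair_is_retained(self, planted_cohort):
        c = planted_cohort
        pfm = encode_pairs(c.expression, [("G0001", "G0002")])
        sel = lasso_select(pfm, c.survival, n_folds=5, seed=1)
        assert sel == [("G0001", "G0002")]

    def test_identical_seed_identical_selection(self, planted_cohort):
        c = planted_cohort
        rng = np.random.default_rng(0)
        decoys = pd.DataFrame(
            rng.binomial(1, 0.5, size=(10, c.expression.shape[1])),
            index=[f"d{i}|e{i}" for i in range(10)], columns=c.expression.columns,
        )
        real = encode_pairs(c.expression, [("G0001", "G0002")]).indicators
        ind = pd.concat([real, decoys])
        pairs = [("G0001", "G0002")] + [(f"d{i}", f"e{i}") for i in range(10)]
        pfm = PairFeatureMatrix(pairs=pairs, indicators=ind)
        a = lasso_select(pfm, c.survival, n_folds=5, seed=33)
        b = lasso_select(pfm, c.survival, n_folds=5, seed=33)
        assert a == b
        assert ("G0001", "G0002") in a


class TestMultivariateFit:
    def test_matches_newton_oracle_on_small_instance(self):
        """Joint 3-covariate fit equals brute-force maximization to 1e-6."""
        rng = np.random.default_rng(8)
        n = 30
        X = rng.binomial(1, 0.5, size=(n, 3)).astype(float)
        eta = X @ np.array([0.8, -0.5, 0.3])
        time = np.round(rng.exponential(50, n) * np.exp(-eta), 6)
        assert len(set(time)) == n
        event = np.ones(n, int)
        rows = [list(X[:, j].astype(int)) for j in range(3)]
        pfm = pfm_from_rows(rows, ["A|B", "C|D", "E|F"])
        model = multivariate_fit(pfm.pairs, pfm, surv_df(time, event),
                                 backward_step=False)
        beta, _ = newton_breslow_cox(X, time, event)
        got = np.array([c for _, c in model.terms])
        assert np.allclose(got, beta, atol=1e-6)

    def test_cutoff_is_brute_force_median_of_training_scores(self):
        rng = np.random.default_rng(2)
        n = 40
        rows = [list(rng.binomial(1, 0.5, n)) for _ in range(2)]
        pfm = pfm_from_rows(rows, ["A|B", "C|D"])
        time = np.round(rng.exponential(100, n), 6)
        model = multivariate_fit(pfm.pairs, pfm, surv_df(time, [1] * n),
                                 backward_step=False)
        coefs = dict(model.terms)
        scores = []
        for s in range(n):
            lin = sum(coefs[p] * pfm.indicators.loc[pair_label(p)].iloc[s] for p in model.pairs)
            scores.append(np.exp(lin))
        assert model.cutoff == pytest.approx(np.median(scores), rel=1e-12)

    def test_empty_selection_reports_no_prognostic_pairs(self):
        pfm = pfm_from_rows([[1, 0, 1, 0, 1, 0]])
        model = multivariate_fit([], pfm, surv_df([1, 2, 3, 4, 5, 6.0], [1] * 6))
        assert model.terms == []
        assert "no prognostic pairs" in model.metadata["note"]


class TestScoring:
    def test_all_zero_indicators_score_exactly_one(self):
        model = published_model()
        genes = model.genes
        # expression where the second gene of every pair dominates -> indicator 0
        expr = pd.DataFrame(
            {g: [float(i)] for i, g in enumerate(genes)}, index=["s1"]
        ).T
        for (a, b), _ in model.terms:
            expr.loc[a, "s1"] = 0.0
            expr.loc[b, "s1"] = 1.0
        scores = score_expression(model, expr)
        assert scores.loc["s1", "linear_sum"] == 0.0
        assert scores.loc["s1", "mkpc_score"] == 1.0
        assert scores.loc["s1", "risk_group"] == "low"

    def test_flipping_one_indicator_multiplies_by_exp_coefficient(self):
        model = published_model()
        pfm = pfm_from_rows([[0], [0], [0], [0], [0], [0], [0]],
                            [pair_label(p) for p in model.pairs])
        base = score_mkpc(model, pfm)
        for j, (pair, coef) in enumerate(model.terms):
            rows = [[0]] * 7
            rows[j] = [1]
            flipped = pfm_from_rows(rows, [pair_label(p) for p in model.pairs])
            sc = score_mkpc(model, flipped)
            assert sc["mkpc_score"].iloc[0] == pytest.approx(
                base["mkpc_score"].iloc[0] * np.exp(coef), rel=1e-15
            )

    def test_score_near_cutoff_classification(self):
        model = published_model()
        # a score of 1.06 against the 1.0544 cutoff must be called high risk
        assert 1.06 > model.cutoff
        pfm = pfm_from_rows([[1], [0], [1], [0], [0], [0], [0]],
                            [pair_label(p) for p in model.pairs])
        sc = score_mkpc(model, pfm)
        expected = np.exp(1.028064 + 0.573201)
        assert sc["mkpc_score"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert sc["risk_group"].iloc[0] == "high"

    def test_missing_gene_error_lists_symbols(self, worked):
        model = published_model()
        with pytest.raises(KeyError, match="MPP2"):
            score_expression(model, worked.expression)


class TestPublishedModel:
    def test_term_count_and_protective_factors(self):
        model = published_model()
        assert len(model.terms) == 7
        negatives = sorted(c for _, c in model.terms if c < 0)
        assert negatives == [-1.09876, -0.57286]

    def test_hazard_ratio_sign_identity(self):
        for _, coef in published_model().terms:
            hr = np.exp(coef)
            assert np.sign(hr - 1) == np.sign(coef)


class TestFunnel:
    def test_counts_monotonically_decrease(self, planted_cohort):
        c = planted_cohort
        rng = np.random.default_rng(5)
        pairs = [("G0001", "G0002")] + [(f"x{i}", f"y{i}") for i in range(12)]
        rows = [encode_pairs(c.expression, [pairs[0]]).indicators.iloc[0].tolist()]
        rows += [list(rng.binomial(1, p, c.expression.shape[1]))
                 for p in rng.uniform(0.05, 0.95, 12)]
        ind = pd.DataFrame(rows, index=[pair_label(p) for p in pairs],
                           columns=c.expression.columns)
        pfm = PairFeatureMatrix(pairs=pairs, indicators=ind)
        model, rep = train_funnel(pfm, c.survival, seed=3)
        d = rep.as_dict()
        assert (d["pairs_enumerated"] >= d["pairs_informative"]
                >= d["pairs_univariate"] >= d["pairs_lasso"] >= d["pairs_final"])
        assert ("G0001", "G0002") in model.pairs
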