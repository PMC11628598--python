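"""Cox screen vs lifelines, log-rank vs risk-set enumeration, elastic net vs IRLS."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from lipidsig.prognosis import (
    cox_multivariable,
    cox_univariate_batch,
    fit_subtype_predictor,
    km_logrank,
    predict_subtype,
    univariate_cox_screen,
)
from lipidsig.simulate import simulate_survival


def irls_logistic(X, y, max_iter=100, tol=1e-12):
    """Unpenalized Newton-Raphson logistic regression oracle."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        grad = Xd.T @ (y - p)
        H = (Xd * W[:, None]).T @ Xd
        step = np.linalg.solve(H, grad)
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def logrank_hand_enumeration(time, event, group):
    """O-E log-rank statistic by explicit risk-set bookkeeping."""
    times = np.sort(np.unique(time[event == 1]))
    O = E = V = 0.0
    for t in times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestCoxUnivariateBatch:
    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.normal(size=(n, 3))
        # month-resolution times force Efron tie handling
        base = simulate_survival(
            (X[:, 0] > 0).astype(int), 2.5, 0.02, 48, seed=1)
        t = np.ceil(base["time_months"].to_numpy())
        e = base["event"].to_numpy()
        fits = cox_univariate_batch(X, t, e)
        for j in range(3):
            df = pd.DataFrame({"t": t, "e": e, "x": X[:, j]})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert fits["coef"][j] == pytest.approx(
                cph.params_["x"], abs=1e-6)
            assert fits["p"][j] == pytest.approx(
                cph.summary["p"]["x"], abs=1e-6)

    def test_planted_driver_retained(self):
        rng = np.random.default_rng(1)
        n = 266
        driver = rng.normal(size=n)
        lab = (driver > 0).astype(int)
        surv = simulate_survival(lab, 3.34, 0.005, 60, seed=2)
        X = pd.DataFrame({
            "driver": driver,
            **{f"noise{i}": rng.normal(size=n) for i in range(5)},
        })
        res = univariate_cox_screen(
            X, surv["time_months"], surv["event"])
        assert "driver" in res.retained
        assert res.table.loc["driver", "hr"] > 1
        assert res.table.loc["driver", "p"] < 1e-3

    def test_constant_lipid_excluded_not_error(self):
        rng = np.random.default_rng(2)
        n = 60
        surv = simulate_survival(np.zeros(n, int), 1.0, 0.02, 60, seed=3)
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        res = univariate_cox_screen(X, surv["time_months"], surv["event"])
        assert "const" in res.excluded
        assert "const" not in res.table.index

    def test_incomplete_survival_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="complete"):
            univariate_cox_screen(X, [1.0, np.nan, 3.0], [1, 0, 1])


class TestKmLogrank:
    def test_identical_groups_null(self):
        t = np.array([5.0, 8, 12, 20, 25, 30] * 2)
        e = np.array([1, 0, 1, 1, 0, 1] * 2)
        g = np.repeat(["A", "B"], 6)
        fit = km_logrank(g, t, e)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)
        assert fit.p == pytest.approx(1.0)

    def test_product_limit_closed_form(self):
        # no censoring: S(t) = (n - deaths by t) / n
        t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        e = np.ones(8, int)
        g = np.repeat(["A", "B"], 4)
        fit = km_logrank(g, t, e, horizons=(2.5,))
        assert fit.survival_at.at["A", 2.5] == pytest.approx(2 / 4)
        assert fit.survival_at.at["B", 2.5] == pytest.approx(1.0)

    def test_statistic_matches_hand_enumeration(self):
        # deaths at (1,2) in A and (3,4) in B, no censoring
        t = np.array([1.0, 2, 3, 4])
        e = np.ones(4, int)
        g = np.array([1, 1, 0, 0])
        expected = logrank_hand_enumeration(t, e, g)
        fit = km_logrank(np.where(g == 1, "A", "B"), t, e)
        assert fit.chi2 == pytest.approx(expected, abs=1e-9)

    def test_zero_event_group_flagged(self):
        t = np.array([5.0, 6, 7, 8, 9, 10])
        e = np.array([1, 1, 1, 0, 0, 0])
        g = np.repeat(["A", "B"], 3)
        fit = km_logrank(g, t, e)
        assert fit.zero_event_groups == ["B"]


class TestCoxMultivariable:
    def test_null_covariate_ci_covers_one(self):
        cover = 0
        n_rep = 100
        for i in range(n_rep):
            rng = np.random.default_rng(3000 + i)
            n = 120
            lab = rng.integers(0, 2, n)
            surv = simulate_survival(lab, 2.0, 0.01, 60, seed=4000 + i)
            df = pd.DataFrame({
                "time_months": surv["time_months"],
                "event": surv["event"],
                "subtype": lab,
                "noise": rng.normal(size=n),
            })
            out = cox_multivariable(df)
            cover += out.at["noise", "ci_low"] <= 1 <= out.at["noise", "ci_high"]
        assert cover / n_rep >= 0.90

    def test_subtype_stays_significant_with_noise_covariates(self):
        hits = 0
        n_rep = 25
        for i in range(n_rep):
            rng = np.random.default_rng(5000 + i)
            lab = rng.integers(0, 2, 266)
            surv = simulate_survival(lab, 3.34, 0.005, 60, seed=6000 + i)
            df = pd.DataFrame({
                "time_months": surv["time_months"],
                "event": surv["event"],
                "subtype": lab,
                "noise1": rng.normal(size=266),
                "noise2": rng.normal(size=266),
            })
            out = cox_multivariable(df)
            hits += out.at["subtype", "p"] < 0.05
        assert hits / n_rep >= 0.80

    def test_duplicated_covariate_collinearity_error(self):
        surv = simulate_survival(np.zeros(50, int), 1.0, 0.02, 60, seed=7)
        x = np.random.default_rng(8).normal(size=50)
        df = pd.DataFrame({
            "time_months": surv["time_months"], "event": surv["event"],
            "a": x, "b": x,
        })
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariable(df)


class TestSubtypePredictor:
    def test_huge_lambda_gives_null_model(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 5))
        y = np.array(["SI"] * 30 + ["SII"] * 50)
        pred = fit_subtype_predictor(X, y, alpha=1.0, lambda_grid=[1e4])
        assert np.allclose(pred.beta, 0.0)
        assert pred.beta0 == pytest.approx(np.log(50 / 30), abs=1e-2)

    def test_zero_lambda_matches_irls_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 5))
        beta_true = np.array([1.0, -0.5, 0.25, 0.0, 0.5])
        p = 1 / (1 + np.exp(-(X @ beta_true - 0.2)))
        y01 = (rng.uniform(size=100) < p).astype(int)
        y = np.where(y01 == 1, "SII", "SI")
        pred = fit_subtype_predictor(X, y, alpha=0.0, lambda_grid=[1e-10])
        ref = irls_logistic(X, y01)
        assert pred.beta0 == pytest.approx(ref[0], abs=1e-4)
        assert np.allclose(pred.beta, ref[1:], atol=1e-4)

    def test_lasso_sparser_than_ridge(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(90, 10))
        y01 = (X[:, 0] + 0.5 * rng.normal(size=90) > 0).astype(int)
        y = np.where(y01 == 1, "SII", "SI")
        lam = 0.05
        lasso = fit_subtype_predictor(X, y, alpha=1.0, lambda_grid=[lam])
        ridge = fit_subtype_predictor(X, y, alpha=0.0, lambda_grid=[lam])
        assert (lasso.beta == 0).sum() >= (ridge.beta == 0).sum()
        assert (ridge.beta == 0).sum() == 0

    def test_predict_probabilities_and_tie_rule(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] > 0, "SII", "SI")
        pred = fit_subtype_predictor(X, y, alpha=0.5, lambda_grid=[0.01])
        probs, labels = predict_subtype(pred, X)
        assert np.allclose(probs.sum(axis=1), 1.0)
        eta = X @ pred.beta + pred.beta0
        assert (labels == np.where(eta > 0, "SII", "SI")).all()
        # exact boundary: eta = 0 resolves to the first class (SI)
        x0 = -pred.beta0 * pred.beta / (pred.beta @ pred.beta)
        _, lab0 = predict_subtype(pred, x0[None, :])
        assert lab0[0] == "SI"

    def test_missing_features_rejected(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = np.where(X["a"] > 0, "SII", "SI")
        pred = fit_subtype_predictor(X, y, lambda_grid=[0.1])
        with pytest.raises(KeyError):
            predict_subtype(pred, X[["a"]])
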