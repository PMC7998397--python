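"""VIF, pruning, backward elimination, OLS diagnostics, regression BF and
RF-based recursive feature elimination."""

import math

import numpy as np
import pandas as pd
import pytest

from dyadkit.modeling import (
    all_subset_bf_select,
    backward_eliminate,
    choose_subset_size,
    ols_fit_diagnostics,
    prune_multicollinearity,
    rf_rfe_cv,
    select_model,
    vif,
    zs_regression_bf,
)


def _corr_design(rng, n, p, rho):
    cov = rho * np.ones((p, p))
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])


def vif_oracle(X: pd.DataFrame) -> pd.Series:
    """Brute-force auxiliary regressions via explicit normal equations."""
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        Z = np.column_stack([np.ones(len(X)), others.to_numpy()])
        yj = X[col].to_numpy()
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        r2 = 1 - resid @ resid / np.sum((yj - yj.mean()) ** 2)
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


class TestVif:
    def test_orthogonal_predictors(self):
        # zero-mean mutually orthogonal harmonics: auxiliary R2 is exactly 0
        t = np.arange(32)
        X = pd.DataFrame({
            "a": np.sin(2 * np.pi * t / 32),
            "b": np.cos(2 * np.pi * t / 32),
            "c": np.sin(4 * np.pi * t / 32),
        })
        assert np.allclose(vif(X), 1.0, atol=1e-10)

    def test_duplicate_predictor_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        v = vif(X)
        assert not np.isfinite(v["a"]) or v["a"] > 1e10

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(2)
        X = _corr_design(rng, 60, 3, 0.6)
        assert np.allclose(vif(X), vif_oracle(X), atol=1e-10)


class TestPruneMulticollinearity:
    def test_noop_when_all_below_threshold(self):
        rng = np.random.default_rng(3)
        X = _corr_design(rng, 60, 3, 0.3)
        kept, trace = prune_multicollinearity(X)
        assert kept == list(X.columns) and trace == []

    def test_near_duplicate_removes_one_of_pair(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=80)
        X = pd.DataFrame({
            "x1": x1, "x2": x1 + rng.normal(0, 0.1, 80),
            "x3": rng.normal(size=80),
        })
        kept, trace = prune_multicollinearity(X)
        assert "x3" in kept
        assert len(kept) == 2
        assert len(trace) == 1
        assert trace[0]["removed"] in ("x1", "x2")
        assert vif(pd.DataFrame(X[kept])).max() <= 4.0

    def test_correlated_chain_terminates_quickly(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=100)
        X = pd.DataFrame({
            f"x{i}": 0.84 * z + rng.normal(0, math.sqrt(1 - 0.7), 100)
            for i in range(3)
        })
        kept, trace = prune_multicollinearity(X)
        assert len(trace) <= 2
        if len(kept) >= 2:
            assert vif(X[kept]).max() <= 4.0


class TestZsRegressionBf:
    def test_strong_single_predictor(self):
        assert zs_regression_bf(0.9, 48, 1) > 100

    def test_grid_oracle_agreement(self):
        def oracle(r2, n, p, s=math.sqrt(2) / 4, steps=2_000_000):
            u = np.linspace(1e-9, 1 - 1e-9, steps)
            g = u / (1 - u)
            jac = 1 / (1 - u) ** 2
            w = (
                (1 + g) ** ((n - 1 - p) / 2)
                * (1 + g * (1 - r2)) ** (-(n - 1) / 2)
                * math.sqrt(n * s * s / 2) / math.gamma(0.5)
                * g ** -1.5 * np.exp(-n * s * s / (2 * g))
            )
            return np.trapezoid(w * jac, u)

        for r2, n, p in [(0.3, 48, 2), (0.7, 24, 4), (0.05, 30, 1)]:
            assert zs_regression_bf(r2, n, p) == pytest.approx(
                oracle(r2, n, p), rel=1e-4
            )

    def test_duplicate_predictor_never_raises_bf(self):
        """Adding a redundant predictor costs a dimensional penalty."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 48
            r2 = rng.uniform(0.05, 0.8)
            p = int(rng.integers(1, 5))
            assert zs_regression_bf(r2, n, p + 1) < zs_regression_bf(r2, n, p)


class TestAllSubsetSelect:
    def test_orthogonalized_noise_prefers_intercept(self):
        """A target with no linear signal at all (residualized against the
        full design) yields bf10 < 1 for every subset."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(48, 4)),
                         columns=[f"x{j}" for j in range(4)])
        y = rng.normal(size=48)
        Z = np.column_stack([np.ones(48), X.to_numpy()])
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        table, best = all_subset_bf_select(y, X)
        assert (table["bf10"] < 1).all()

    def test_pure_noise_usually_prefers_intercept(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(size=(48, 4)),
                             columns=[f"x{j}" for j in range(4)])
            y = rng.normal(size=48)
            table, _ = all_subset_bf_select(y, X)
            hits += table["bf10"].max() < 1
        assert hits > 10

    def test_true_predictor_selected(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(48, 4)),
                         columns=[f"x{j}" for j in range(4)])
        y = 1.2 * X["x1"].to_numpy() + rng.normal(0, 0.5, 48)
        table, best = all_subset_bf_select(y, X)
        assert "x1" in best

    def test_cap_enforced(self):
        X = pd.DataFrame(np.zeros((30, 21)))
        with pytest.raises(ValueError, match="pre-screen"):
            all_subset_bf_select(np.arange(30.0), X)


class TestBackwardEliminate:
    def test_all_significant_unchanged(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = X @ np.array([1.0, 1.0, 1.0]) + rng.normal(0, 0.3, 60)
        kept, trace = backward_eliminate(y, X)
        assert kept == list("abc") and trace == []

    def test_noise_predictor_removed(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = 2.0 * X["a"] + 2.0 * X["b"] + rng.normal(0, 0.3, 60)
        kept, trace = backward_eliminate(y, X)
        assert kept == ["a", "b"]
        assert [t["removed"] for t in trace] == ["c"]

    def test_one_at_a_time_matches_exhaustive_refit_oracle(self):
        """The iterative rule equals an oracle that refits from scratch at
        every step on the current survivor set."""
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"x{j}" for j in range(5)])
        y = X["x0"] * 1.5 + X["x1"] * 0.8 + rng.normal(0, 1.0, 40)

        cols = list(X.columns)
        while cols:
            fit = ols_fit_diagnostics(y, X[cols])
            pv = fit.coefficients["p"].drop("Intercept")
            if pv.max() < 0.1:
                break
            cols = [c for c in cols if c != pv.idxmax()]
        kept, _ = backward_eliminate(y, X)
        assert kept == cols


class TestOlsFitDiagnostics:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_fit_diagnostics(2 * x + 1, pd.DataFrame({"x": x}))
        assert fit.coefficients.loc["Intercept", "b"] == pytest.approx(1.0)
        assert fit.coefficients.loc["x", "b"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rse == pytest.approx(0.0, abs=1e-10)

    def test_coefficient_recovery_within_2se(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(48, 3)), columns=list("abc"))
        beta = np.array([0.8, -0.5, 0.3])
        y = 1.0 + X @ beta + rng.normal(0, 0.4, 48)
        fit = ols_fit_diagnostics(y, X)
        import statsmodels.api as sm
        se = sm.OLS(y, sm.add_constant(X)).fit().bse
        for name, b_true, s in zip("abc", beta, se[list("abc")]):
            assert abs(fit.coefficients.loc[name, "b"] - b_true) < 2 * s

    def test_balanced_duplicated_rows_no_influence_outliers(self):
        rng = np.random.default_rng(13)
        X0 = rng.normal(size=(12, 2))
        X = pd.DataFrame(np.vstack([X0, X0]), columns=list("ab"))
        y = X["a"].to_numpy() + rng.normal(0, 0.2, 24)
        fit = ols_fit_diagnostics(y, X)
        assert (fit.cooks_distance < 4 / len(X) * 4).all()

    def test_singular_design_names_columns(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            ols_fit_diagnostics(x, X)

    def test_bic_ranking_matches_exhaustive_rss_oracle(self):
        """BIC ordering over subsets equals the n*ln(RSS/n)+(p+2)*ln(n)
        oracle ordering (same additive constant for all models)."""
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] * 1.0 + rng.normal(0, 0.5, 40)
        import itertools
        bics, oracle = [], []
        for k in (1, 2, 3):
            for sub in itertools.combinations("abc", k):
                sub = list(sub)
                fit = ols_fit_diagnostics(y, X[sub])
                Z = np.column_stack([np.ones(40), X[sub].to_numpy()])
                beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
                rss = float(np.sum((y - Z @ beta) ** 2))
                bics.append(fit.bic)
                oracle.append(40 * math.log(rss / 40) + (k + 2) * math.log(40))
        assert np.argsort(bics).tolist() == np.argsort(oracle).tolist()
        diffs = np.array(bics) - np.array(oracle)
        assert np.allclose(diffs, diffs[0])


class TestSelectModelPipeline:
    def test_gates_hold_on_recovered_model(self):
        rng = np.random.default_rng(15)
        X = _corr_design(rng, 48, 8, 0.3)
        y = X.iloc[:, :4] @ (0.5 * np.ones(4)) + rng.normal(0, 0.7, 48)
        sel = select_model(y.to_numpy(), X)
        assert sel.fit.max_vif is None or sel.fit.max_vif <= 4.0
        pv = sel.fit.coefficients["p"].drop("Intercept")
        assert (pv < 0.1).all()


class TestRfRfeCv:
    def test_strong_pair_recovered(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(48, 5)),
                         columns=[f"x{j}" for j in range(5)])
        y = X["x0"] + X["x1"] + rng.normal(0, 0.3, 48)
        res = rf_rfe_cv(y.to_numpy(), X, repeats=2, n_estimators=80, seed=0)
        assert {"x0", "x1"} <= set(res.chosen_predictors) or \
            list(res.importances.index[:2]) in (["x0", "x1"], ["x1", "x0"])
        assert {"x0", "x1"} <= set(res.importances.index[:3])

    def test_resample_count(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + rng.normal(0, 0.5, 20)
        res = rf_rfe_cv(y, X, folds=4, repeats=2, n_estimators=30, seed=1)
        assert (res.per_size_metrics["n_resamples"] == 8).all()

    def test_duplicate_predictors_equal_importance(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x.copy(),
                          "c": rng.normal(size=30)})
        y = x + rng.normal(0, 0.3, 30)
        res = rf_rfe_cv(y, X, folds=3, repeats=2, n_estimators=120, seed=2)
        ia, ib = res.importances["a"], res.importances["b"]
        assert abs(ia - ib) < 0.5 * max(ia, ib)

    def test_parsimony_rule_flat_rmse_chooses_one(self):
        per_size = pd.DataFrame({
            "rmse_mean": [1.00, 1.01, 0.99, 1.00],
        }, index=[1, 2, 3, 4])
        assert choose_subset_size(per_size, 0.05) == 1

    def test_parsimony_rule_respects_tolerance(self):
        per_size = pd.DataFrame({
            "rmse_mean": [2.0, 1.2, 1.0],
        }, index=[1, 2, 3])
        assert choose_subset_size(per_size, 0.05) == 3
        assert choose_subset_size(per_size, 0.25) == 2
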