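"""Outcome-model pipeline: Bayesian all-subset selection, collinearity
pruning, backward elimination, OLS diagnostics and RF-based recursive
feature elimination under repeated cross-validation.

The regression Bayes factor is the Zellner-Siow mixture-of-g-priors default:
for a subset of p covariates with coefficient of determination R^2 at sample
size n,

    BF10 = int_0^inf (1+g)^((n-1-p)/2) * (1+g*(1-R^2))^(-(n-1)/2) pi(g) dg

with g/ (n * s^2) ~ InverseGamma(1/2, 1/2) for prior scale s (the
conventional "medium" scale for continuous covariates is sqrt(2)/4).
Evaluated by adaptive quadrature.

The collinearity pruning iterates: take the predictor X1 with the highest
VIF; find X2, the predictor most correlated with it; drop X1 if removing it
leaves VIF(X2) <= threshold, otherwise drop whichever of the pair has the
highest correlation with any third predictor; repeat until max VIF is at or
below the threshold.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedKFold
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "OlsFit",
    "ModelSelection",
    "RfeResult",
    "vif",
    "zs_regression_bf",
    "all_subset_bf_select",
    "prune_multicollinearity",
    "backward_eliminate",
    "ols_fit_diagnostics",
    "select_model",
    "rf_rfe_cv",
    "choose_subset_size",
    "DEFAULT_REGRESSION_RSCALE",
    "MAX_SUBSET_PREDICTORS",
]

#: Zellner-Siow prior scale for continuous covariates ("medium")
DEFAULT_REGRESSION_RSCALE = math.sqrt(2.0) / 4.0

#: exhaustive subset cap (2^20 models)
MAX_SUBSET_PREDICTORS = 20


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1-R2_j) regressing each
    column on the others (with intercept).  Perfect collinearity yields
    ``inf``."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    Z = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = [variance_inflation_factor(Z, j + 1) for j in range(X.shape[1])]
    return pd.Series(vals, index=X.columns, name="VIF")


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """OLS R^2 of y on X (intercept added); NaN for singular designs."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta, res, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        return float("nan")
    resid = y - Z @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def zs_regression_bf(
    r2: float,
    n: int,
    p: int,
    rscale: float = DEFAULT_REGRESSION_RSCALE,
    *,
    epsrel: float = 1e-6,
) -> float:
    """Zellner-Siow regression Bayes factor vs the intercept-only model."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("need 0 <= R2 < 1")
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    s2 = rscale * rscale

    def integrand(g: float) -> float:
        return (
            (1.0 + g) ** ((n - 1 - p) / 2.0)
            * (1.0 + g * (1.0 - r2)) ** (-(n - 1) / 2.0)
            * math.sqrt(n * s2 / 2.0) / math.gamma(0.5)
            * g ** -1.5
            * math.exp(-n * s2 / (2.0 * g))
        )

    val, err = integrate.quad(integrand, 0, np.inf, epsrel=epsrel, limit=300)
    if not np.isfinite(val) or val <= 0:
        raise RuntimeError("regression BF quadrature failed")
    return val


@dataclass
class OlsFit:
    """OLS fit with the diagnostics the pipeline gates on."""

    predictors: list[str]
    coefficients: pd.DataFrame      # columns: b, t, p (index incl. Intercept)
    F: float
    df_num: int
    df_den: int
    p: float
    rse: float
    r2: float
    adj_r2: float
    bic: float
    cooks_distance: np.ndarray
    durbin_watson: float
    resid_normal_p: float
    resid_homoscedastic_p: float
    max_vif: float | None


def ols_fit_diagnostics(y, X) -> OlsFit:
    """Fit y ~ X by OLS and report inference plus assumption diagnostics.

    BIC follows the Gaussian maximum-likelihood convention counting the
    intercept, slopes and error variance as parameters:
    ``-2*logLik + log(n)*(p+2)``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    Z = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Z.to_numpy(dtype=float)) < Z.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax() if p > 1 else (X.columns[0],)
        raise ValueError(f"singular design; dependent columns near {pair}")
    fit = sm.OLS(y, Z).fit()
    coef = pd.DataFrame(
        {"b": fit.params, "t": fit.tvalues, "p": fit.pvalues}
    ).rename(index={"const": "Intercept"})
    rss = float(fit.ssr)
    llf = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    bic = -2.0 * llf + math.log(n) * (p + 2)
    influence = fit.get_influence()
    resid = fit.resid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw_p = float(stats.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 0.0
        bp = sm.stats.diagnostic.het_breuschpagan(resid, Z)
    return OlsFit(
        predictors=list(X.columns),
        coefficients=coef,
        F=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p=float(fit.f_pvalue),
        rse=math.sqrt(rss / fit.df_resid),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        bic=bic,
        cooks_distance=influence.cooks_distance[0],
        durbin_watson=float(durbin_watson(resid)),
        resid_normal_p=sw_p,
        resid_homoscedastic_p=float(bp[1]),
        max_vif=float(vif(X).max()) if p >= 2 else None,
    )


@dataclass
class ModelSelection:
    candidate_models: pd.DataFrame   # columns: predictors (tuple), p, r2, bf10
    selected: list[str]
    fit: OlsFit
    bf10: float
    pruning_trace: list[dict] = field(default_factory=list)

    @property
    def max_vif(self) -> float | None:
        return self.fit.max_vif


def all_subset_bf_select(
    y,
    X: pd.DataFrame,
    rscale: float = DEFAULT_REGRESSION_RSCALE,
) -> tuple[pd.DataFrame, list[str]]:
    """Score every non-empty predictor subset by its Zellner-Siow BF vs the
    intercept-only model; return (table of all subsets, maximal-BF subset).

    Subsets with singular designs are skipped with a warning.  Raises for
    more than :data:`MAX_SUBSET_PREDICTORS` candidates (pre-screen first).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    p_all = len(names)
    if p_all > MAX_SUBSET_PREDICTORS:
        raise ValueError(
            f"{p_all} candidates exceed the exhaustive cap of "
            f"{MAX_SUBSET_PREDICTORS}; pre-screen the predictor set first"
        )
    if np.ptp(y) == 0:
        raise ValueError("zero variance target")
    Xa = X.to_numpy(dtype=float)
    rows = []
    for k in range(1, p_all + 1):
        for subset in itertools.combinations(range(p_all), k):
            r2 = _r2(y, Xa[:, subset])
            if math.isnan(r2):
                warnings.warn(
                    f"singular design for subset {[names[j] for j in subset]}; skipped"
                )
                continue
            bf = zs_regression_bf(min(max(r2, 0.0), 1 - 1e-12), len(y), k, rscale)
            rows.append(
                {"predictors": tuple(names[j] for j in subset), "p": k,
                 "r2": r2, "bf10": bf}
            )
    table = pd.DataFrame(rows)
    best = table.loc[table["bf10"].idxmax(), "predictors"]
    return table, list(best)


def prune_multicollinearity(
    X: pd.DataFrame,
    *,
    vif_threshold: float = 4.0,
    corr_limit: float = 0.600,
) -> tuple[list[str], list[dict]]:
    """Iteratively remove predictors until max VIF <= threshold.

    Returns the surviving predictor names and a trace of removals, each with
    the rule that fired (``vif`` when the top-VIF predictor itself is
    dropped, ``correlation-pair`` when its partner is dropped instead).
    """
    X = pd.DataFrame(X).copy()
    trace: list[dict] = []
    while X.shape[1] >= 2:
        v = vif(X)
        if v.max() <= vif_threshold:
            break
        x1 = v.idxmax()
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        x2 = corr[x1].idxmax()
        pair_r = float(corr.loc[x1, x2])
        vif_without_x1 = (
            vif(X.drop(columns=[x1]))[x2] if X.shape[1] > 2 else 1.0
        )
        if vif_without_x1 <= vif_threshold:
            drop, rule = x1, "vif"
        else:
            others = [c for c in X.columns if c not in (x1, x2)]
            max_r = {
                c: float(corr.loc[c, others].max()) if others else 0.0
                for c in (x1, x2)
            }
            drop = max(max_r, key=max_r.get)
            rule = "correlation-pair"
        trace.append(
            {"removed": drop, "rule": rule, "vif": float(v[x1]),
             "pair": (x1, x2), "pair_r": pair_r,
             "above_corr_limit": pair_r >= corr_limit}
        )
        X = X.drop(columns=[drop])
        if X.shape[1] < 1:
            raise ValueError("pruning removed every predictor")
    return list(X.columns), trace


def backward_eliminate(
    y,
    X: pd.DataFrame,
    *,
    p_out: float = 0.1,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop the highest-p predictor with p >= ``p_out``,
    refitting after each removal.  Returns survivors and the removal trace;
    an empty survivor list (with a warning) means intercept-only."""
    X = pd.DataFrame(X).copy()
    trace: list[dict] = []
    while X.shape[1] >= 1:
        fit = ols_fit_diagnostics(y, X)
        pvals = fit.coefficients["p"].drop("Intercept")
        worst = pvals.idxmax()
        if pvals[worst] < p_out:
            return list(X.columns), trace
        trace.append({"removed": worst, "rule": "backward-p",
                      "p": float(pvals[worst])})
        X = X.drop(columns=[worst])
    warnings.warn("backward elimination removed every predictor")
    return [], trace


def select_model(
    y,
    X: pd.DataFrame,
    *,
    rscale: float = DEFAULT_REGRESSION_RSCALE,
    vif_threshold: float = 4.0,
    corr_limit: float = 0.600,
    p_out: float = 0.1,
) -> ModelSelection:
    """Full pipeline: all-subset BF selection, collinearity pruning,
    backward elimination, final OLS fit with diagnostics and the final
    model's BF recomputed on its own subset."""
    X = pd.DataFrame(X)
    table, best = all_subset_bf_select(y, X, rscale)
    kept = best
    trace: list[dict] = []
    if len(kept) >= 2:
        kept, trace = prune_multicollinearity(
            X[kept], vif_threshold=vif_threshold, corr_limit=corr_limit
        )
    survivors, btrace = backward_eliminate(y, X[kept], p_out=p_out)
    trace.extend(btrace)
    if not survivors:
        survivors = [max(kept, key=lambda c: abs(np.corrcoef(np.asarray(y, float), X[c])[0, 1]))]
    fit = ols_fit_diagnostics(y, X[survivors])
    bf = zs_regression_bf(min(fit.r2, 1 - 1e-12), len(np.asarray(y)), len(survivors), rscale)
    return ModelSelection(
        candidate_models=table, selected=survivors, fit=fit, bf10=bf,
        pruning_trace=trace,
    )


def choose_subset_size(per_size_metrics: pd.DataFrame, rmse_tolerance: float = 0.05) -> int:
    """Parsimony rule: the smallest subset size whose mean RMSE is within
    ``rmse_tolerance`` (relative) of the best mean RMSE."""
    rmse = per_size_metrics["rmse_mean"]
    ok = rmse.index[rmse <= (1.0 + rmse_tolerance) * rmse.min()]
    return int(min(ok))


@dataclass
class RfeResult:
    per_size_metrics: pd.DataFrame   # index size; columns rmse/r2/mae mean & sd
    importances: pd.Series
    chosen_size: int
    chosen_predictors: list[str]


def rf_rfe_cv(
    y,
    X: pd.DataFrame,
    *,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    rmse_tolerance: float = 0.05,
    n_estimators: int = 500,
    importance_repeats: int = 5,
) -> RfeResult:
    """Recursive feature elimination with random forests under repeated CV.

    For each of ``folds x repeats`` resamples, predictors are ranked by RF
    permutation importance on the training part and nested subsets (top-1,
    top-2, ...) are scored on the held-out fold.  RMSE/R2/MAE are aggregated
    per subset size; the chosen size is the smallest whose mean RMSE is
    within ``rmse_tolerance`` of the best mean RMSE.  The forest uses
    ``n_estimators`` trees, about p/3 features per split and a minimum leaf
    size of 5.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 15 or p < 2:
        raise ValueError("need n >= 15 and p >= 2")
    names = list(X.columns)
    max_feat = max(1, p // 3)

    def _forest(rs):
        return RandomForestRegressor(
            n_estimators=n_estimators, max_features=max_feat,
            min_samples_leaf=5, random_state=rs, n_jobs=1,
        )

    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    metrics: dict[int, list[tuple[float, float, float]]] = {
        k: [] for k in range(1, p + 1)
    }
    imp_acc = np.zeros(p)
    n_resamples = 0
    for split_i, (tr, te) in enumerate(rkf.split(X)):
        y_tr, y_te = y[tr], y[te]
        if np.ptp(y_tr) == 0 or np.ptp(y_te) == 0:
            warnings.warn(f"resample {split_i}: no variance in y; skipped")
            continue
        n_resamples += 1
        rs = seed * 100003 + split_i
        rf = _forest(rs).fit(X.iloc[tr], y_tr)
        perm = permutation_importance(
            rf, X.iloc[tr], y_tr, n_repeats=importance_repeats,
            random_state=rs, n_jobs=1,
        )
        imp = perm.importances_mean
        imp_acc += imp
        ranking = np.argsort(-imp)
        for k in range(1, p + 1):
            cols = [names[j] for j in ranking[:k]]
            sub = _forest(rs).fit(X.iloc[tr][cols], y_tr)
            pred = sub.predict(X.iloc[te][cols])
            err = y_te - pred
            rmse = float(np.sqrt(np.mean(err ** 2)))
            mae = float(np.mean(np.abs(err)))
            if np.ptp(pred) > 0:
                r2 = float(np.corrcoef(y_te, pred)[0, 1] ** 2)
            else:
                r2 = float("nan")
            metrics[k].append((rmse, r2, mae))

    rows = {}
    for k, vals in metrics.items():
        arr = np.array(vals, dtype=float)
        rows[k] = {
            "rmse_mean": np.nanmean(arr[:, 0]), "rmse_sd": np.nanstd(arr[:, 0], ddof=1),
            "r2_mean": np.nanmean(arr[:, 1]), "r2_sd": np.nanstd(arr[:, 1], ddof=1),
            "mae_mean": np.nanmean(arr[:, 2]), "mae_sd": np.nanstd(arr[:, 2], ddof=1),
            "n_resamples": len(vals),
        }
    per_size = pd.DataFrame(rows).T
    per_size.index.name = "size"
    chosen_size = choose_subset_size(per_size, rmse_tolerance)
    importances = pd.Series(imp_acc / max(n_resamples, 1), index=names).sort_values(
        ascending=False
    )
    chosen = list(importances.index[:chosen_size])
    return RfeResult(per_size, importances, chosen_size, chosen)
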