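"""Univariate statistics: assumption screening, paired comparisons,
effect sizes, correlations and default Bayes factors.

The Bayes factors are the Jeffreys-Zellner-Siow (JZS) defaults: a Cauchy
prior on the standardized effect size for the one-sample (paired) t-test,
and a stretched-beta prior on the population correlation for the
correlation test.  Both are evaluated by adaptive quadrature, not by
approximation formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "assumption_screen",
    "compare_paired",
    "effect_size_r2",
    "pearson_test",
    "jzs_ttest_bf",
    "jzs_correlation_bf",
    "bf_interpret",
    "DEFAULT_TTEST_RSCALE",
    "DEFAULT_CORRELATION_KAPPA",
]

#: Cauchy prior scale for the paired-test JZS Bayes factor
DEFAULT_TTEST_RSCALE = math.sqrt(2.0) / 2.0

#: stretched-beta prior width for the correlation Bayes factor ("medium")
DEFAULT_CORRELATION_KAPPA = 1.0 / 3.0


@dataclass
class ComparisonResult:
    variable: str
    test_used: str               # "paired_t" | "wilcoxon_signed_rank"
    statistic: float | None      # t, or V (sum of positive ranks)
    df: int | None               # t-test only
    p: float | None              # two-sided
    r2: float | None
    bf10: float | None
    evidence_label: str | None
    normal: bool | None = None   # Shapiro gate outcome on the differences
    degenerate: bool = False


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float
    bf10: float
    evidence_label: str


def assumption_screen(
    x: np.ndarray,
    groups: "list[np.ndarray] | None" = None,
    *,
    alpha: float = 0.05,
) -> dict:
    """Normality (Shapiro-Wilk) and, when groups are given, homogeneity of
    variances (Levene).  Constant input is non-normal by convention."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    out: dict = {"alpha": alpha}
    if np.ptp(x) == 0:
        warnings.warn("constant input: treated as non-normal")
        out.update(normal=False, shapiro_p=None)
    else:
        p_sw = float(stats.shapiro(x).pvalue)
        out.update(normal=p_sw > alpha, shapiro_p=p_sw)
    if groups is not None:
        p_lev = float(stats.levene(*groups).pvalue)
        out.update(homoscedastic=p_lev > alpha, levene_p=p_lev)
    return out


def effect_size_r2(t: float, df: float) -> float:
    """r^2 = t^2 / (t^2 + df), the variance-explained effect size for a
    t statistic."""
    if df <= 0:
        raise ValueError("df must be positive")
    return t * t / (t * t + df)


def jzs_ttest_bf(
    t: float,
    n: int,
    rscale: float = DEFAULT_TTEST_RSCALE,
    *,
    epsrel: float = 1e-6,
) -> float:
    """One-sample JZS Bayes factor BF10 from a t statistic.

    Under H1 the standardized effect delta has a Cauchy(0, rscale) prior,
    equivalently delta | g ~ N(0, g*rscale^2) with g ~ InverseGamma(1/2,
    1/2).  The marginal likelihood ratio is evaluated by adaptive
    quadrature over g; symmetric in the sign of t.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    nu = n - 1
    t2 = t * t

    def integrand(g: float) -> float:
        ngr = 1.0 + n * g * rscale * rscale
        return (
            ngr ** -0.5
            * (1.0 + t2 / (ngr * nu)) ** (-(nu + 1) / 2.0)
            * g ** -1.5
            * math.exp(-1.0 / (2.0 * g))
            / math.sqrt(2.0 * math.pi)
        )

    num, err = integrate.quad(integrand, 0, np.inf, epsrel=epsrel, limit=200)
    if num <= 0 or not np.isfinite(num) or (num > 0 and err / num > 1e-3):
        raise RuntimeError(
            f"quadrature failed to converge (value={num}, abserr={err})"
        )
    den = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    return num / den


def _corr_kernel(rho: float, r: float, n: int) -> float:
    """Marginal likelihood of the sample correlation r given rho, up to a
    rho-free constant (exact sampling-distribution kernel)."""
    return (
        (1.0 - rho * rho) ** ((n - 1) / 2.0)
        * (1.0 - rho * r) ** (-(2.0 * n - 3.0) / 2.0)
        * special.hyp2f1(0.5, 0.5, (2.0 * n - 1.0) / 2.0, (rho * r + 1.0) / 2.0)
    )


def jzs_correlation_bf(
    r: float,
    n: int,
    kappa: float = DEFAULT_CORRELATION_KAPPA,
    *,
    epsrel: float = 1e-6,
) -> float:
    """Bayes factor for a correlation under a stretched-beta prior on rho.

    The prior is rho = 2*B - 1 with B ~ Beta(1/kappa, 1/kappa); kappa = 1/3
    is the conventional "medium" width, kappa = 1 the uniform prior.
    Evaluated by quadrature over rho; symmetric in the sign of r.
    """
    if not -1.0 < r < 1.0:
        warnings.warn("|r| = 1: infinite evidence, BF unbounded")
        return math.inf
    if n < 3:
        raise ValueError("need n >= 3")
    a = 1.0 / kappa
    log_beta = special.betaln(a, a)

    def prior(rho: float) -> float:
        return 0.5 * math.exp(
            (a - 1) * (math.log((1 + rho) / 2) + math.log((1 - rho) / 2))
            - log_beta
        )

    num, err = integrate.quad(
        lambda rho: _corr_kernel(rho, r, n) * prior(rho),
        -1.0, 1.0, epsrel=epsrel, limit=200,
    )
    if num <= 0 or not np.isfinite(num):
        raise RuntimeError("correlation BF quadrature failed")
    return num / _corr_kernel(0.0, r, n)


_BANDS = [
    (100.0, "extreme evidence for H1"),
    (30.0, "very strong evidence for H1"),
    (10.0, "strong evidence for H1"),
    (3.0, "moderate evidence for H1"),
    (1.0, "anecdotal evidence for H1"),
]


def bf_interpret(bf10: float) -> str:
    """Evidence label on the conventional Jeffreys bands as revised by
    Lee & Wagenmakers; mirrored below 1 for evidence favoring H0."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 == 1.0:
        return "no evidence"
    if bf10 > 1.0:
        for cut, label in _BANDS:
            if bf10 > cut:
                return label
        return "anecdotal evidence for H1"
    inv = 1.0 / bf10
    for cut, label in _BANDS:
        if inv > cut:
            return label.replace("H1", "H0")
    return "anecdotal evidence for H0"


def _signed_rank_v(d: np.ndarray) -> tuple[float, float]:
    """(V, Z): sum of positive ranks of the nonzero differences and its
    continuity-corrected standardization under H0 (mid-ranks for ties,
    tie-corrected variance)."""
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return v, 0.0
    z = (v - mu - 0.5 * np.sign(v - mu)) / math.sqrt(sigma2)
    return v, float(z)


def compare_paired(
    x_t0: np.ndarray,
    x_t1: np.ndarray,
    *,
    variable: str = "",
    alpha: float = 0.05,
    rscale: float = DEFAULT_TTEST_RSCALE,
    force_test: str | None = None,
    exact_threshold: int = 25,
) -> ComparisonResult:
    """Paired comparison of T0 vs T1 with assumption-gated test choice.

    The paired t on differences is used when the differences pass the
    Shapiro-Wilk gate; otherwise the Wilcoxon signed-rank test (V = sum of
    positive ranks) with exact p for n <= ``exact_threshold`` without ties
    or zeros, else the normal approximation with continuity correction.
    The effect size is r^2 = t^2/(t^2+df) for the t branch and (Z/sqrt(n))^2
    for the Wilcoxon branch; BF10 is the JZS Bayes factor computed from the
    t statistic of the differences in both branches.
    """
    x0 = np.asarray(x_t0, dtype=float)
    x1 = np.asarray(x_t1, dtype=float)
    if x0.shape != x1.shape:
        raise ValueError("paired vectors must have equal length")
    n = x0.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x0 - x1
    if np.ptp(d) == 0 and d[0] == 0:
        warnings.warn("all differences are zero: comparison degenerate")
        return ComparisonResult(
            variable, "paired_t", None, None, None, None, None, None,
            degenerate=True,
        )

    screen = assumption_screen(d, alpha=alpha)
    use_t = screen["normal"] if force_test is None else (force_test == "paired_t")

    sd = d.std(ddof=1)
    if sd == 0:  # constant nonzero differences
        t_stat = math.inf if d.mean() > 0 else -math.inf
        bf10 = math.inf
    else:
        t_stat = float(d.mean() / (sd / math.sqrt(n)))
        bf10 = jzs_ttest_bf(t_stat, n, rscale)

    if use_t:
        df = n - 1
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        r2 = effect_size_r2(t_stat, df) if np.isfinite(t_stat) else 1.0
        return ComparisonResult(
            variable, "paired_t", t_stat, df, p, r2, bf10,
            bf_interpret(bf10), normal=screen["normal"],
        )

    nz = d[d != 0]
    v, z = _signed_rank_v(d)
    if nz.size <= exact_threshold and nz.size == n:
        res = stats.wilcoxon(x0, x1, correction=True, method="exact")
    else:
        res = stats.wilcoxon(x0, x1, correction=True, method="approx")
    p = float(res.pvalue)
    r2 = (z / math.sqrt(n)) ** 2  # convention: squared standardized V
    return ComparisonResult(
        variable, "wilcoxon_signed_rank", v, None, p, r2, bf10,
        bf_interpret(bf10), normal=screen["normal"],
    )


def pearson_test(
    x: np.ndarray,
    y: np.ndarray,
    *,
    kappa: float = DEFAULT_CORRELATION_KAPPA,
) -> CorrelationResult:
    """Pearson correlation with t test and correlation Bayes factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    n = x.size
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    df = n - 2
    if 1.0 - abs(r) < 1e-10:  # numerically perfect correlation
        r = math.copysign(1.0, r)
        t = math.copysign(math.inf, r)
        p = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bf10 = math.inf
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
        bf10 = jzs_correlation_bf(r, n, kappa)
    label = bf_interpret(bf10) if np.isfinite(bf10) else "extreme evidence for H1"
    return CorrelationResult(r, t, df, p, bf10, label)
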