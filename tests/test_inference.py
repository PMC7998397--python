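"""Assumption screening, paired tests, effect sizes and Bayes factors."""

import math

import numpy as np
import pytest
from scipy import special, stats

from dyadkit.inference import (
    assumption_screen,
    bf_interpret,
    compare_paired,
    effect_size_r2,
    jzs_correlation_bf,
    jzs_ttest_bf,
    pearson_test,
)


def jzs_grid_oracle(t, n, rscale=math.sqrt(2) / 2, steps=2_000_000):
    """Dense-grid Riemann oracle for the one-sample JZS Bayes factor,
    integrating over g via the compactifying substitution g = u/(1-u)."""
    nu = n - 1
    u = np.linspace(1e-9, 1 - 1e-9, steps)
    g = u / (1 - u)
    jac = 1.0 / (1 - u) ** 2
    ngr = 1 + n * g * rscale ** 2
    integrand = (
        ngr ** -0.5
        * (1 + t * t / (ngr * nu)) ** (-(nu + 1) / 2)
        * g ** -1.5 * np.exp(-1 / (2 * g)) / math.sqrt(2 * math.pi)
    ) * jac
    num = np.trapezoid(integrand, u)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den


class TestAssumptionScreen:
    def test_heavy_tailed_mixture_fails_normality(self):
        rng = np.random.default_rng(123)
        x = np.where(rng.random(24) < 0.85, rng.normal(0, 1, 24),
                     rng.normal(0, 12, 24))
        assert assumption_screen(x)["normal"] is False

    def test_exact_normal_quantiles_pass(self):
        q = stats.norm.ppf(np.linspace(0.02, 0.98, 24))
        assert assumption_screen(q)["normal"] is True

    def test_equal_variance_groups_homoscedastic(self):
        rng = np.random.default_rng(5)
        g1, g2 = rng.normal(0, 1, 40), rng.normal(0.3, 1, 40)
        out = assumption_screen(g1, groups=[g1, g2])
        assert out["homoscedastic"] is True

    def test_constant_input_non_normal(self):
        with pytest.warns(UserWarning, match="constant"):
            assert assumption_screen(np.ones(10))["normal"] is False


class TestEffectSizeR2:
    @pytest.mark.parametrize("t,r2", [
        (2.669, 0.236), (3.305, 0.322), (-3.788, 0.384), (3.206, 0.309),
        (-4.140, 0.427), (-3.982, 0.408), (2.857, 0.262), (-2.862, 0.263),
        (2.828, 0.258), (-2.147, 0.167), (2.355, 0.194), (-3.483, 0.345),
        (2.162, 0.169), (1.794, 0.123), (-4.059, 0.417),
    ])
    def test_reproduces_printed_triples_at_df_23(self, t, r2):
        assert effect_size_r2(t, 23) == pytest.approx(r2, abs=5e-4)

    def test_zero_t(self):
        assert effect_size_r2(0.0, 23) == 0.0


class TestJzsTtestBf:
    @pytest.mark.parametrize("t,bf", [
        (2.669, 3.717), (-4.059, 66.246), (3.305, 13.142),
        (-3.788, 36.647), (-3.982, 55.914), (3.206, 10.726),
    ])
    def test_reproduces_reported_values(self, t, bf):
        assert jzs_ttest_bf(t, 24) == pytest.approx(bf, rel=0.005)

    def test_null_t_favors_h0(self):
        assert jzs_ttest_bf(0.0, 24) < 1.0

    def test_sign_symmetry(self):
        assert jzs_ttest_bf(2.5, 24) == pytest.approx(jzs_ttest_bf(-2.5, 24))

    def test_monotone_in_abs_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
        bfs = [jzs_ttest_bf(t, 24) for t in ts]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t,n", [(2.0, 10), (3.5, 24), (0.8, 48)])
    def test_agrees_with_grid_oracle(self, t, n):
        got = jzs_ttest_bf(t, n)
        oracle = jzs_grid_oracle(t, n)
        assert got == pytest.approx(oracle, rel=1e-4)


class TestCorrelationBf:
    def test_null_r_favors_h0(self):
        assert jzs_correlation_bf(0.0, 48) < 1.0

    def test_sign_symmetry(self):
        for r in (0.1, 0.37, 0.8):
            assert jzs_correlation_bf(r, 48) == pytest.approx(
                jzs_correlation_bf(-r, 48), rel=1e-9
            )

    def test_matches_independent_rho_grid(self):
        """Dense-grid oracle over rho with the exact sampling density."""
        r, n, kappa = -0.37, 48, 1 / 3
        rho = np.linspace(-0.9999, 0.9999, 400001)
        a = 1 / kappa
        prior = 0.5 * ((1 + rho) / 2) ** (a - 1) * ((1 - rho) / 2) ** (a - 1) \
            / special.beta(a, a)
        kern = (
            (1 - rho ** 2) ** ((n - 1) / 2)
            * (1 - rho * r) ** (-(2 * n - 3) / 2)
            * special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)
        )
        oracle = np.trapezoid(kern * prior, rho) / special.hyp2f1(
            0.5, 0.5, (2 * n - 1) / 2, 0.5
        )
        assert jzs_correlation_bf(r, n) == pytest.approx(oracle, rel=1e-4)

    def test_perfect_correlation_warns(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert jzs_correlation_bf(1.0, 20) == math.inf


class TestBfInterpret:
    @pytest.mark.parametrize("bf,label", [
        (3.717, "moderate evidence for H1"),
        (66.246, "very strong evidence for H1"),
        (1.0, "no evidence"),
        (12.0, "strong evidence for H1"),
        (150.0, "extreme evidence for H1"),
        (0.2, "moderate evidence for H0"),
        (0.005, "extreme evidence for H0"),
    ])
    def test_bands(self, bf, label):
        assert bf_interpret(bf) == label


class TestComparePaired:
    def test_exact_wilcoxon_enumeration_n3(self):
        res = compare_paired([1, 2, 3], [2, 3, 4], force_test="wilcoxon")
        assert res.test_used == "wilcoxon_signed_rank"
        assert res.statistic == 0.0  # V: no positive ranks
        assert res.p == pytest.approx(0.25)  # 2/8 sign patterns

    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = compare_paired([1.0, 2, 3], [1.0, 2, 3])
        assert res.degenerate and res.statistic is None

    def test_t_branch_on_normal_differences(self):
        rng = np.random.default_rng(8)
        x0 = rng.normal(0, 1, 24)
        x1 = x0 + rng.normal(0.8, 0.5, 24)
        res = compare_paired(x0, x1)
        assert res.test_used == "paired_t"
        assert res.df == 23 and res.p < 0.01
        assert res.r2 == pytest.approx(
            effect_size_r2(res.statistic, 23), abs=1e-12
        )
        # BF must be the JZS value at the same t
        assert res.bf10 == pytest.approx(jzs_ttest_bf(res.statistic, 24))

    def test_exact_and_approx_wilcoxon_agree_at_n25(self):
        rng = np.random.default_rng(17)
        x0 = rng.normal(0, 1, 25)
        x1 = x0 + rng.normal(0.3, 1.0, 25)
        exact = compare_paired(x0, x1, force_test="wilcoxon", exact_threshold=25)
        approx = compare_paired(x0, x1, force_test="wilcoxon", exact_threshold=0)
        assert exact.statistic == approx.statistic
        assert abs(exact.p - approx.p) < 0.01

    def test_type_one_error_calibration(self):
        """Under a true null the gated test rejects at about alpha."""
        rng = np.random.default_rng(99)
        rej = 0
        reps = 2000
        for _ in range(reps):
            x0 = rng.normal(0, 1, 24)
            x1 = x0 + rng.normal(0, 1, 24)
            res = compare_paired(x0, x1)
            if res.p is not None and res.p < 0.05:
                rej += 1
        assert 0.04 <= rej / reps <= 0.06


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_test(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=48)
        y = 0.4 * x + rng.normal(size=48)
        res = pearson_test(x, y)
        r_direct = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        assert res.t == pytest.approx(
            r_direct * math.sqrt(46) / math.sqrt(1 - r_direct ** 2), abs=1e-12
        )
        assert res.df == 46

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_test(np.ones(5), np.arange(5.0))
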