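"""LP quantile fit: exactness, subgradient optimality, R1, AIC, bootstrap."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lichenrisk.quantile import (
    bootstrap_fits,
    compare_models,
    fit_quantile_regression,
    pinball_loss,
    polynomial_design,
    qr_aic,
    r1_statistic,
)


def brute_force_objective(y, X, tau):
    """Oracle: exhaustive search over all p-point interpolating fits.

    An optimal basic solution of the quantile LP interpolates p
    observations, so the minimum over all invertible p-subsets equals the
    LP optimum.
    """
    n, p = X.shape
    best = np.inf
    for idx in itertools.combinations(range(n), p):
        sub = X[list(idx)]
        if abs(np.linalg.det(sub)) < 1e-10:
            continue
        beta = np.linalg.solve(sub, y[list(idx)])
        best = min(best, pinball_loss(y - X @ beta, tau))
    return best


class TestFitExactCases:
    def test_constant_response_intercept_only(self):
        y = np.full(20, 7.0)
        fit = fit_quantile_regression(y, np.ones((20, 1)), tau=0.9)
        assert fit.coef[0] == pytest.approx(7.0)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)

    def test_two_point_interpolation_and_intercept_null(self):
        # y={0,10} at x={0,1}: slope model interpolates (V=0); the
        # intercept-only tau=0.9 objective 0.1*c + 0.9*(10-c) is minimized
        # at c=10 with value 1
        y = np.array([0.0, 10.0])
        X = np.column_stack([np.ones(2), np.array([0.0, 1.0])])
        fit = fit_quantile_regression(y, X, tau=0.9)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)
        assert fit.coef == pytest.approx([0.0, 10.0])
        y3 = np.array([0.0, 10.0, 5.0])
        null = fit_quantile_regression(y3[:2], np.ones((2, 1)), tau=0.9)
        assert null.coef[0] == pytest.approx(10.0)
        assert null.objective == pytest.approx(1.0)

    def test_intercept_estimates_sample_quantile(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=501)
        fit = fit_quantile_regression(y, np.ones((501, 1)), tau=0.9)
        # LP solution is an order statistic near the 90th percentile
        assert abs(fit.coef[0] - np.quantile(y, 0.9)) < 0.05

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_quantile_regression(np.arange(10.0), X, names=["a", "b", "c"])

    def test_invalid_tau_and_nonfinite(self):
        with pytest.raises(ValueError):
            fit_quantile_regression(np.arange(5.0), np.ones((5, 1)), tau=1.0)
        y = np.arange(5.0)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_quantile_regression(y, np.ones((5, 1)))


class TestOptimality:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 16))
        x = rng.uniform(0, 10, n)
        X = np.column_stack([np.ones(n), x])
        y = 5 + 2 * x + rng.normal(0, 3, n)
        for tau in (0.5, 0.9):
            fit = fit_quantile_regression(y, X, tau=tau)
            assert fit.objective == pytest.approx(
                brute_force_objective(y, X, tau), abs=1e-8
            )

    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.9])
    def test_residual_sign_bracketing(self, tau):
        rng = np.random.default_rng(99)
        n = 400
        x = rng.uniform(0, 10, n)
        X = np.column_stack([np.ones(n), x, x**2])
        y = 20 - x + rng.exponential(3, n)
        fit = fit_quantile_regression(y, X, tau=tau)
        assert fit.n_negative <= tau * n + 1e-9
        assert fit.n_positive <= (1 - tau) * n + 1e-9

    def test_matches_statsmodels_quantreg(self):
        # independent implementation cross-check
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 12, 500)
        X = np.column_stack([np.ones(500), x, x**2])
        y = np.round((30 - 3 * x + 0.05 * x**2) * rng.uniform(0, 1 / 0.9, 500))
        ours = fit_quantile_regression(y, X, tau=0.9)
        theirs = sm.QuantReg(y, X).fit(q=0.9)
        # objectives comparable (solvers differ; ours is the LP optimum)
        assert ours.objective <= pinball_loss(y - X @ theirs.params, 0.9) + 1e-6
        assert ours.predict(X).mean() == pytest.approx(
            float(np.mean(X @ theirs.params)), rel=0.02
        )

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=15, deadline=None)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 60)
        X = np.column_stack([np.ones(60), x])
        y = 10 - x + rng.normal(0, 1, 60)
        base = fit_quantile_regression(y, X, tau=0.9)
        scaled = fit_quantile_regression(scale * y, X, tau=0.9)
        assert scaled.coef == pytest.approx(scale * base.coef, rel=1e-5, abs=1e-7)
        assert scaled.objective == pytest.approx(scale * base.objective, rel=1e-6)
        null = fit_quantile_regression(y, np.ones((60, 1)), tau=0.9)
        null_s = fit_quantile_regression(scale * y, np.ones((60, 1)), tau=0.9)
        assert r1_statistic(scaled, null_s) == pytest.approx(
            r1_statistic(base, null), abs=1e-6
        )


class TestR1:
    def test_model_equals_null_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0, 10.0])
        null = fit_quantile_regression(y, np.ones((4, 1)), tau=0.9)
        assert r1_statistic(null, null) == pytest.approx(0.0)

    def test_perfect_fit_gives_one(self):
        y = np.array([0.0, 10.0])
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        fit = fit_quantile_regression(y, X, tau=0.9)
        null = fit_quantile_regression(y, np.ones((2, 1)), tau=0.9)
        assert r1_statistic(fit, null) == pytest.approx(1.0)

    def test_zero_null_objective_undefined(self):
        y = np.full(5, 3.0)
        null = fit_quantile_regression(y, np.ones((5, 1)), tau=0.9)
        with pytest.warns(UserWarning):
            assert r1_statistic(null, null) is None


class TestAIC:
    def test_delta_depends_only_on_n_p_and_objective_ratio(self):
        # AIC_a - AIC_b = 2n log(V_a/V_b) + 2(p_a - p_b), algebraically
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 300)
        y = 20 - x + rng.exponential(2, 300)
        f1 = fit_quantile_regression(y, np.ones((300, 1)), tau=0.9)
        X2 = np.column_stack([np.ones(300), x])
        f2 = fit_quantile_regression(y, X2, tau=0.9)
        expected = 2 * 300 * np.log(f1.objective / f2.objective) + 2 * (f1.p - f2.p)
        assert qr_aic(f1) - qr_aic(f2) == pytest.approx(expected, abs=1e-9)

    def test_identical_objectives_prefer_smaller_model(self):
        # same V-hat, 3 extra parameters -> delta AIC = 6 < 25: keep simpler
        rng = np.random.default_rng(4)
        y = rng.normal(10, 1, 100)
        small = fit_quantile_regression(y, np.ones((100, 1)), tau=0.9)
        big = small.__class__(
            coef=np.r_[small.coef, 0, 0, 0], objective=small.objective,
            tau=0.9, n=100, p=4, names=["a", "b", "c", "d"],
            residuals=small.residuals,
        )
        assert qr_aic(big) - qr_aic(small) == pytest.approx(6.0)
        sel = compare_models([small, big], threshold=25)
        assert sel["selected_index"] == 0

    def test_real_deposition_effect_selected(self, metric_dataset):
        # with a configured deposition effect, deposition+climate beats
        # climate-only by far more than the delta-AIC bar of 25
        _, _, sites, _, _ = metric_dataset
        x = sites["deposition"].to_numpy()
        clim = sites[["mean_annual_precip_mm", "mean_max_aug_temp_c"]].to_numpy()
        y = sites["forage_abundance"].to_numpy()
        Xc = np.column_stack([np.ones(len(x)), clim])
        Xdc = np.column_stack([np.ones(len(x)), x, x**2, clim])
        fc = fit_quantile_regression(y, Xc, tau=0.9)
        fdc = fit_quantile_regression(y, Xdc, tau=0.9)
        sel = compare_models([fc, fdc], threshold=25)
        assert sel["selected_index"] == 1
        assert qr_aic(fc) - qr_aic(fdc) > 25

    def test_pure_noise_keeps_simpler_model(self):
        # no deposition effect: the richer nested model rarely clears 25
        kept_simple = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.2, 12, 300)
            y = rng.poisson(20, 300).astype(float)
            f0 = fit_quantile_regression(y, np.ones((300, 1)), tau=0.9)
            X, _ = polynomial_design(x, 2)
            f1 = fit_quantile_regression(y, X, tau=0.9)
            if compare_models([f0, f1], threshold=25)["selected_index"] == 0:
                kept_simple += 1
        assert kept_simple >= 19

    def test_perfect_fit_sentinel(self):
        y = np.array([0.0, 10.0])
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        fit = fit_quantile_regression(y, X, tau=0.9)
        assert qr_aic(fit) == float("-inf")


class TestBootstrap:
    def test_seed_reproducible(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 80)
        X = np.column_stack([np.ones(80), x])
        y = 10 - 0.5 * x + rng.normal(0, 1, 80)
        b1 = bootstrap_fits(y, X, n_reps=2, seed=5)
        b2 = bootstrap_fits(y, X, n_reps=2, seed=5)
        np.testing.assert_array_equal(b1.coef, b2.coef)

    def test_band_ordering(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 80)
        X = np.column_stack([np.ones(80), x])
        y = 10 - 0.5 * x + rng.normal(0, 1, 80)
        boot = bootstrap_fits(y, X, n_reps=50, seed=5)
        grid = np.column_stack([np.ones(30), np.linspace(0, 10, 30)])
        lo, hi = boot.band(grid)
        assert np.all(lo <= hi)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_fits(np.arange(10.0), np.ones((10, 1)), n_reps=1, seed=0)


def test_polynomial_design_raw_powers():
    X, names = polynomial_design(np.array([2.0]), degree=3)
    np.testing.assert_allclose(X, [[1.0, 2.0, 4.0, 8.0]])
    assert names == ["intercept", "deposition", "deposition^2", "deposition^3"]
    with pytest.raises(ValueError):
        polynomial_design(np.array([1.0]), degree=0)
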