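"""Quantile-regression engine: exact solutions, oracle equivalence,
quantile properties, equivariance and asymptotic inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalgrowth.errors import (
    ConvergenceError,
    DegenerateSparsityError,
    InvalidParameterError,
    SingularContrastError,
    SingularDesignError,
)
from fetalgrowth.qr_engine import (
    DesignMatrix,
    QuantileFit,
    coefficient_covariance,
    fit_quantile,
    fit_quantile_set,
    hall_sheather_bandwidth,
    pinball_loss,
    wald_test,
)


def brute_force_objective(X, y, tau):
    """Independent oracle: the optimum of the pinball LP lies at a vertex
    where p residuals vanish, so enumerate all exactly-interpolating
    coefficient vectors and take the best objective."""
    n, p = X.shape
    best = np.inf
    for idx in itertools.combinations(range(n), p):
        sub = X[list(idx)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, y[list(idx)])
        best = min(best, pinball_loss(y - X @ beta, tau))
    return best


class TestPinballLoss:
    @pytest.mark.parametrize("residuals,tau,expected", [
        ([0, 0, 0], 0.5, 0.0),
        ([1, -1], 0.5, 1.0),
        ([2, -3], 0.25, 2.75),       # 0.25*2 + 0.75*3
        ([-2.0], 0.9, 0.2),
    ])
    def test_values(self, residuals, tau, expected):
        assert pinball_loss(residuals, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_tau_out_of_range(self, tau):
        with pytest.raises(InvalidParameterError):
            pinball_loss([1.0], tau)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
           st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_nonnegative_and_zero_iff_zero(self, residuals, tau):
        loss = pinball_loss(residuals, tau)
        assert loss >= 0.0
        if all(r == 0 for r in residuals):
            assert loss == 0.0


class TestFitQuantile:
    def test_intercept_only_median(self):
        X = DesignMatrix(np.ones((3, 1)), ("intercept",))
        fit = fit_quantile(X, [1.0, 2.0, 9.0], 0.5)
        assert fit.beta == pytest.approx([2.0])
        assert fit.objective == pytest.approx(4.0)

    def test_degenerate_tau_optimum_is_order_statistic_interval(self):
        # any value in [1, 2] minimises the tau=0.25 loss of y=[1,2,3,4];
        # the solver must land on the optimal objective (vertex choice may
        # differ between backends)
        X = DesignMatrix(np.ones((4, 1)), ("intercept",))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_quantile(X, y, 0.25)
        assert 1.0 - 1e-8 <= fit.beta[0] <= 2.0 + 1e-8
        assert fit.objective == pytest.approx(brute_force_objective(
            np.ones((4, 1)), y, 0.25), abs=1e-10)

    def test_two_points_interpolated_exactly(self):
        X = DesignMatrix(np.column_stack([np.ones(2), [0.0, 1.0]]),
                         ("intercept", "x"))
        fit = fit_quantile(X, [3.0, 5.0], 0.3)
        assert fit.objective == pytest.approx(0.0, abs=1e-9)
        assert fit.beta == pytest.approx([3.0, 2.0])

    def test_matches_brute_force_on_small_instances(self, rng):
        for n, p in [(5, 1), (8, 2), (12, 2)]:
            for _ in range(5):
                X = np.column_stack([np.ones(n)] +
                                    [rng.normal(size=n) for _ in range(p - 1)])
                y = rng.normal(size=n)
                for tau in (0.1, 0.25, 0.5, 0.9):
                    fit = fit_quantile(DesignMatrix(X, tuple(
                        f"c{i}" for i in range(p))), y, tau)
                    assert fit.objective == pytest.approx(
                        brute_force_objective(X, y, tau), abs=1e-8)

    def test_matches_statsmodels_on_moderate_problem(self, rng):
        # independent implementation cross-check
        import statsmodels.api as sm

        x = rng.normal(size=400)
        y = 1.0 + 2.0 * x + rng.standard_t(4, 400)
        X = np.column_stack([np.ones(400), x])
        fit = fit_quantile(DesignMatrix(X, ("intercept", "x")), y, 0.25)
        ref = sm.QuantReg(y, X).fit(q=0.25)
        assert fit.beta == pytest.approx(ref.params, abs=1e-4)
        assert fit.objective <= pinball_loss(y - X @ ref.params, 0.25) + 1e-6

    def test_quantile_property_intercept_only(self, rng):
        for tau in (0.1, 0.3, 0.5, 0.8):
            y = rng.normal(size=137)
            X = DesignMatrix(np.ones((y.size, 1)), ("intercept",))
            fit = fit_quantile(X, y, tau)
            r = y - fit.beta[0]
            assert (r < 0).mean() <= tau + 1e-12
            assert (r <= 0).mean() >= tau - 1e-12

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        X = DesignMatrix(np.column_stack([np.ones(80), x]), ("intercept", "x"))
        base = fit_quantile(X, y, 0.3)
        shifted = fit_quantile(X, 5.0 + 2.5 * y, 0.3)
        assert shifted.beta[0] == pytest.approx(5.0 + 2.5 * base.beta[0],
                                                abs=1e-6)
        assert shifted.beta[1] == pytest.approx(2.5 * base.beta[1], abs=1e-6)

    def test_heteroscedastic_spread_orders_slopes(self, rng):
        x = rng.uniform(0.5, 3.0, 600)
        y = x * (1.0 + rng.normal(0, 0.5, 600))  # spread grows with x
        X = DesignMatrix(np.column_stack([np.ones(600), x]), ("intercept", "x"))
        lo, hi = fit_quantile_set(X, y, [0.1, 0.9], compute_cov=False)
        assert hi.beta[1] > lo.beta[1]

    def test_symmetric_noise_gives_symmetric_intercepts(self, rng):
        y = rng.normal(0.0, 1.0, 4000)
        X = DesignMatrix(np.ones((y.size, 1)), ("intercept",))
        q25, q50, q75 = (f.beta[0] for f in
                         fit_quantile_set(X, y, [0.25, 0.5, 0.75],
                                          compute_cov=False))
        assert (q75 - q50) == pytest.approx(q50 - q25, abs=0.08)

    def test_rank_deficient_design_raises(self):
        X = DesignMatrix(np.column_stack([np.ones(5), np.ones(5)]),
                         ("a", "b"))
        with pytest.raises(SingularDesignError):
            fit_quantile(X, np.arange(5.0), 0.5)

    def test_duplicate_taus_rejected(self):
        X = DesignMatrix(np.ones((5, 1)), ("intercept",))
        with pytest.raises(InvalidParameterError):
            fit_quantile_set(X, np.arange(5.0), [0.5, 0.5])


class TestCovarianceAndWald:
    def test_sparsity_estimate_matches_normal_density(self, rng):
        # at tau=0.5 with standard-normal errors s(0.5) = 1/phi(0) = sqrt(2*pi)
        y = rng.normal(size=400_000)
        X = DesignMatrix(np.ones((y.size, 1)), ("intercept",))
        fit = QuantileFit(tau=0.5, beta=np.array([np.median(y)]),
                          names=("intercept",), n_obs=y.size,
                          objective=pinball_loss(y - np.median(y), 0.5),
                          converged=True)
        coefficient_covariance(fit, X, y)
        assert fit.sparsity == pytest.approx(np.sqrt(2 * np.pi), rel=0.03)

    def test_response_scaling_scales_covariance(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        X = DesignMatrix(np.column_stack([np.ones(200), x]), ("intercept", "x"))
        f1 = fit_quantile(X, y, 0.5)
        f2 = fit_quantile(X, 3.0 * y, 0.5)
        assert f2.cov == pytest.approx(9.0 * f1.cov, rel=1e-6)

    def test_ci_coverage_for_known_slope(self, rng):
        # 95% CI for a known coefficient under i.i.d. errors
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=150)
            y = 1.0 + 0.5 * x + rng.normal(size=150)
            X = DesignMatrix(np.column_stack([np.ones(150), x]),
                             ("intercept", "x"))
            fit = fit_quantile(X, y, 0.5)
            se = fit.se()[1]
            hits += abs(fit.beta[1] - 0.5) <= 1.96 * se
        assert 0.90 <= hits / reps <= 0.99

    def test_wald_identity_contrast_is_squared_t(self, rng):
        x = rng.normal(size=120)
        y = 1.0 + x + rng.normal(size=120)
        X = DesignMatrix(np.column_stack([np.ones(120), x]), ("intercept", "x"))
        fit = fit_quantile(X, y, 0.5)
        chi, df, p = wald_test(fit, [[0.0, 1.0]])
        assert df == 1
        assert chi == pytest.approx((fit.beta[1] / fit.se()[1]) ** 2, rel=1e-9)
        assert 0.0 <= p <= 1.0

    def test_wald_null_p_roughly_uniform(self, rng):
        # joint test of group indicators with no group effect
        from scipy.stats import kstest

        pvals = []
        for _ in range(60):
            g = rng.integers(0, 3, 240)
            x = rng.normal(size=240)
            y = x + rng.normal(size=240)
            X = np.column_stack([np.ones(240), x,
                                 (g == 1).astype(float),
                                 (g == 2).astype(float)])
            fit = fit_quantile(DesignMatrix(
                X, ("intercept", "x", "g1", "g2")), y, 0.5)
            C = np.zeros((2, 4))
            C[0, 2] = 1.0
            C[1, 3] = 1.0
            pvals.append(wald_test(fit, C)[2])
        assert kstest(pvals, "uniform").pvalue > 0.005

    def test_singular_contrast_raises(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        X = DesignMatrix(np.column_stack([np.ones(60), x]), ("intercept", "x"))
        fit = fit_quantile(X, y, 0.5)
        with pytest.raises(SingularContrastError):
            wald_test(fit, [[0.0, 1.0], [0.0, 2.0]])

    def test_degenerate_residual_spread_raises(self):
        X = DesignMatrix(np.ones((10, 1)), ("intercept",))
        fit = QuantileFit(tau=0.5, beta=np.array([1.0]), names=("intercept",),
                          n_obs=10, objective=0.0, converged=True)
        with pytest.raises(DegenerateSparsityError):
            coefficient_covariance(fit, X, np.ones(10))

    def test_hall_sheather_bandwidth_shrinks_with_n(self):
        assert hall_sheather_bandwidth(10_000, 0.5) < \
            hall_sheather_bandwidth(100, 0.5)
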