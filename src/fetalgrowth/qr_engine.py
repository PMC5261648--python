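"""Linear quantile regression by pinball-loss minimisation.

The conditional tau-quantile of a response ``y`` given regressors ``X`` is
estimated by minimising the asymmetric absolute (pinball) loss

    rho_tau(r) = r * (tau - 1{r < 0}),

which is solved exactly as a linear program: split the residuals into
non-negative parts ``u, v`` with ``y - X beta = u - v`` and minimise
``tau * sum(u) + (1 - tau) * sum(v)``.  The optimum is a vertex of the
feasible polytope, so at a solution (for a full-rank n x p design) p
residuals are exactly zero.  No distributional assumption is made; asymmetry
and kurtosis of the fitted conditional distribution follow the data.

Standard errors use the classical i.i.d.-error asymptotics: the coefficient
covariance is ``tau (1 - tau) s(tau)^2 (X'X)^{-1}`` where the sparsity
``s(tau)`` (reciprocal error density at the tau-quantile) is estimated by a
difference quotient of empirical residual quantiles at the Hall-Sheather
bandwidth.  Linear hypotheses on the coefficients are tested with Wald
chi-square statistics.

The solver runs on internally centred/scaled regressors for conditioning and
reports coefficients and the objective on the original scale.  At degenerate
sample sizes (tau * n integral) the minimiser may not be unique; different
backends can return different vertices with identical objective value — the
contract here is the objective, not the solver path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.stats import chi2, norm

from .errors import (
    ConvergenceError,
    DegenerateSparsityError,
    InvalidParameterError,
    SingularContrastError,
    SingularDesignError,
)

__all__ = [
    "DesignMatrix",
    "QuantileFit",
    "pinball_loss",
    "fit_quantile",
    "fit_quantile_set",
    "coefficient_covariance",
    "hall_sheather_bandwidth",
    "wald_test",
]


@dataclass(frozen=True)
class DesignMatrix:
    """A fully observed n x p regressor matrix with unique column names."""

    X: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "names", tuple(self.names))
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise InvalidParameterError(
                f"design has {X.shape[1]} columns but {len(self.names)} names")
        if len(set(self.names)) != len(self.names):
            raise InvalidParameterError("design column names must be unique")
        if X.shape[1] < 1:
            raise InvalidParameterError("design needs at least one column")
        if not np.all(np.isfinite(X)):
            raise InvalidParameterError("design contains missing/non-finite cells")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class QuantileFit:
    """Result of one quantile-level fit."""

    tau: float
    beta: np.ndarray
    names: tuple[str, ...]
    n_obs: int
    objective: float
    converged: bool
    cov: np.ndarray | None = None
    sparsity: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta

    def se(self) -> np.ndarray:
        if self.cov is None:
            raise InvalidParameterError("covariance has not been estimated")
        return np.sqrt(np.diag(self.cov))


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise InvalidParameterError(f"tau must lie in (0, 1), got {tau}")
    return tau


def pinball_loss(residuals, tau: float) -> float:
    """Total pinball loss sum_i rho_tau(r_i); zero iff all residuals are zero."""
    tau = _check_tau(tau)
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def fit_quantile(X: DesignMatrix, y, tau: float, *, compute_cov: bool = True,
                 tol: float = 1e-9) -> QuantileFit:
    """Minimise the pinball loss of ``y - X beta`` at quantile level ``tau``.

    Raises :class:`SingularDesignError` for rank-deficient designs and
    :class:`ConvergenceError` (with solver diagnostics) if the LP backend
    fails to certify optimality.
    """
    tau = _check_tau(tau)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.n, X.p
    if y.shape[0] != n:
        raise InvalidParameterError("response length does not match design rows")
    if n < p:
        raise SingularDesignError(f"{n} rows < {p} columns")
    if np.linalg.matrix_rank(X.X) < p:
        raise SingularDesignError("design matrix is rank deficient")

    # centre/scale non-constant columns for conditioning; map back afterwards
    col_sd = X.X.std(axis=0)
    col_mean = X.X.mean(axis=0)
    const = col_sd <= 1e-12
    has_intercept = bool(np.any(const & (np.abs(col_mean) > 1e-12)))
    scale = np.where(const, 1.0, col_sd)
    center = np.where(const, 0.0, col_mean) if has_intercept else np.zeros(p)
    Xs = (X.X - center) / scale
    y_scale = float(y.std())
    if y_scale <= 0.0:
        y_scale = 1.0
    ys = y / y_scale

    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sp.hstack([sp.csr_matrix(Xs), sp.eye(n), -sp.eye(n)], format="csr")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=ys, bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": tol,
                           "dual_feasibility_tolerance": tol})
    if res.status != 0:
        raise ConvergenceError(
            f"LP did not converge (status {res.status}: {res.message})",
            diagnostics={"status": res.status, "message": res.message,
                         "tau": tau, "n": n, "p": p})

    beta_s = res.x[:p] * y_scale
    beta = beta_s / scale
    if has_intercept:
        # constant absorbed by centring goes back into the intercept column
        shift = float(np.sum(beta_s * center / scale))
        icol = int(np.flatnonzero(const)[0])
        beta[icol] -= shift / X.X[0, icol]

    objective = pinball_loss(y - X.X @ beta, tau)
    fit = QuantileFit(tau=tau, beta=beta, names=X.names, n_obs=n,
                      objective=objective, converged=True)
    if compute_cov:
        try:
            coefficient_covariance(fit, X, y)
        except DegenerateSparsityError as exc:
            # e.g. saturated fits with zero residual spread; inference is
            # unavailable but the point estimate stands
            fit.diagnostics["covariance"] = str(exc)
    return fit


def fit_quantile_set(X: DesignMatrix, y, taus, *, compute_cov: bool = True
                     ) -> list[QuantileFit]:
    """Fit one quantile per level; ``taus`` must be strictly increasing."""
    taus = [float(t) for t in taus]
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise InvalidParameterError("taus must be strictly increasing (no duplicates)")
    return [fit_quantile(X, y, t, compute_cov=compute_cov) for t in taus]


def hall_sheather_bandwidth(n: int, tau: float, alpha: float = 0.05) -> float:
    """Hall-Sheather bandwidth for the sparsity difference quotient."""
    tau = _check_tau(tau)
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_t = norm.ppf(tau)
    return float(n ** (-1.0 / 3.0) * z_a ** (2.0 / 3.0)
                 * (1.5 * norm.pdf(z_t) ** 2 / (2.0 * z_t ** 2 + 1.0)) ** (1.0 / 3.0))


def coefficient_covariance(fit: QuantileFit, X: DesignMatrix, y,
                           alpha: float = 0.05) -> np.ndarray:
    """Asymptotic i.i.d.-error covariance tau(1-tau) s(tau)^2 (X'X)^{-1}.

    The sparsity s(tau) = 1/f(F^{-1}(tau)) is the difference quotient of
    empirical residual quantiles over a Hall-Sheather bandwidth.  Stores the
    matrix on ``fit.cov`` and returns it.
    """
    y = np.asarray(y, dtype=float).ravel()
    resid = y - X.X @ fit.beta
    n = resid.size
    h = hall_sheather_bandwidth(n, fit.tau, alpha)
    lo, hi = fit.tau - h, fit.tau + h
    if lo <= 0.0 or hi >= 1.0:
        # shrink to stay inside (0,1); quantiles this extreme have thin data anyway
        h = min(fit.tau, 1.0 - fit.tau) / 2.0
        lo, hi = fit.tau - h, fit.tau + h
    q_hi, q_lo = np.quantile(resid, [hi, lo])
    if q_hi <= q_lo:
        raise DegenerateSparsityError(
            f"residual quantile spread non-positive over bandwidth {h:.4g}")
    sparsity = float((q_hi - q_lo) / (2.0 * h))
    xtx_inv = np.linalg.inv(X.X.T @ X.X)
    cov = fit.tau * (1.0 - fit.tau) * sparsity ** 2 * xtx_inv
    cov = (cov + cov.T) / 2.0
    fit.cov = cov
    fit.sparsity = sparsity
    return cov


def wald_test(fit: QuantileFit, contrast) -> tuple[float, int, float]:
    """Wald chi-square test of C beta = 0.

    Returns ``(chi_square, df, p)`` with ``df`` the number of contrast rows.
    """
    if fit.cov is None:
        raise InvalidParameterError("fit has no covariance; estimate it first")
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    if C.shape[1] != fit.beta.size:
        raise InvalidParameterError("contrast has wrong number of columns")
    if np.linalg.matrix_rank(C) < C.shape[0]:
        raise SingularContrastError("contrast rows are linearly dependent")
    mid = C @ fit.cov @ C.T
    if np.linalg.matrix_rank(mid) < mid.shape[0]:
        raise SingularContrastError("C cov C' is singular")
    cb = C @ fit.beta
    stat = float(cb @ np.linalg.solve(mid, cb))
    df = C.shape[0]
    return stat, df, float(chi2.sf(stat, df))
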