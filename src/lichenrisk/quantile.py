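"""Quantile regression of lichen metrics on deposition and climate.

The conditional 90th percentile of a community metric, not its mean, is the
response of interest: maximal metric values are taken to be limited by air
quality alone, while sub-maximal values reflect climate, substrate, habitat
and observer limitations.  Fits minimise the pinball (check) loss

    rho_tau(u) = u * (tau - 1[u < 0])

and are solved exactly as a linear program (the bounded dual form, which is
small: n box-constrained variables and p equality constraints).  Model
comparison uses the asymmetric-Laplace AIC convention, and goodness of fit
is the R1 statistic of Koenker and Machado: one minus the ratio of the
fitted model's pinball objective to the intercept-only objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "QuantileFit",
    "BootstrapResult",
    "polynomial_design",
    "fit_quantile_regression",
    "r1_statistic",
    "qr_aic",
    "compare_models",
    "bootstrap_fits",
]

#: objective must be within this of the LP optimum (HiGHS is an exact solver,
#: so this is a guard on post-hoc recomputation, not a solver tolerance)
OBJECTIVE_TOL = 1e-8


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    """Sum of check-loss values rho_tau(u) = u*(tau - 1[u<0])."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


@dataclass
class QuantileFit:
    """One fitted tau-quantile regression.

    ``objective`` is the minimised pinball sum V-hat; ``coef`` is ordered as
    ``names``.  ``residuals`` are y - X beta.
    """

    coef: np.ndarray
    objective: float
    tau: float
    n: int
    p: int
    names: list[str]
    residuals: np.ndarray
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef

    @property
    def _sign_tol(self) -> float:
        # interpolated observations carry O(eps)-scale residuals; treat them
        # as zero when counting strict signs for the subgradient condition
        scale = float(np.max(np.abs(self.residuals), initial=1.0))
        return 1e-9 * max(1.0, scale)

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.residuals < -self._sign_tol))

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.residuals > self._sign_tol))


@dataclass
class BootstrapResult:
    """Pairs-bootstrap replicate coefficients for one model."""

    coef: np.ndarray           # (n_kept, p)
    tau: float
    n_reps: int
    n_dropped: int
    seed: int
    names: list[str] = field(default_factory=list)

    def band(self, X: np.ndarray, lower: float = 2.5, upper: float = 97.5):
        """Pointwise percentile band of the fitted line on design ``X``."""
        X = np.asarray(X, dtype=float)
        preds = X @ self.coef.T                       # (m, n_kept)
        lo = np.percentile(preds, lower, axis=1)
        hi = np.percentile(preds, upper, axis=1)
        return lo, hi


def polynomial_design(
    deposition: np.ndarray,
    degree: int = 2,
    climate: np.ndarray | None = None,
    climate_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix of raw deposition powers plus optional climate columns.

    Raw (non-orthogonalised) powers are used deliberately so the fitted
    coefficients are directly the polynomial inverted by the critical-load
    machinery.
    """
    x = np.asarray(deposition, dtype=float)
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")
    cols = [np.ones_like(x)] + [x**k for k in range(1, degree + 1)]
    names = ["intercept"] + [
        "deposition" if k == 1 else f"deposition^{k}" for k in range(1, degree + 1)
    ]
    if climate is not None:
        climate = np.atleast_2d(np.asarray(climate, dtype=float))
        if climate.shape[0] != x.shape[0]:
            climate = climate.T
        for j in range(climate.shape[1]):
            cols.append(climate[:, j])
        if climate_names is None:
            climate_names = [f"climate{j}" for j in range(climate.shape[1])]
        names.extend(climate_names)
    return np.column_stack(cols), names


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n < p:
        raise ValueError(f"need n >= p, got n={n}, p={p}")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(p) if diag[j] <= tol]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"collinear columns include: {bad or names}"
        )


def fit_quantile_regression(
    y: np.ndarray,
    X: np.ndarray,
    tau: float = 0.9,
    names: Sequence[str] | None = None,
) -> QuantileFit:
    """Exact tau-quantile regression by linear programming.

    Solves min_beta sum_i rho_tau(y_i - x_i'beta) through the dual LP

        max  y'd   s.t.  X'd = 0,  -(1-tau) <= d_i <= tau,

    whose equality-constraint marginals recover beta.  At an optimal basic
    solution the fitted hyperplane interpolates p observations and the
    residual signs satisfy the subgradient condition
    #(u<0) <= tau*n and #(u>0) <= (1-tau)*n.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    _check_design(X, names)
    n, p = X.shape

    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=np.zeros(p),
        bounds=[(-(1.0 - tau), tau)] * n,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    beta = -np.asarray(res.eqlin.marginals, dtype=float)
    resid = y - X @ beta
    obj = pinball_loss(resid, tau)
    # duality: primal objective must match the dual optimum
    converged = abs(obj - (-res.fun)) <= max(OBJECTIVE_TOL, 1e-9 * (1 + abs(obj)))
    return QuantileFit(
        coef=beta, objective=obj, tau=tau, n=n, p=p,
        names=names, residuals=resid, converged=converged,
    )


def r1_statistic(fit: QuantileFit, null_fit: QuantileFit) -> float | None:
    """R1 = 1 - V(model)/V(intercept-only); None if the null objective is 0."""
    if fit.tau != null_fit.tau:
        raise ValueError("fits must share tau")
    if fit.n != null_fit.n:
        raise ValueError("fits must share the response")
    if null_fit.objective <= 0.0:
        import warnings

        warnings.warn("intercept-only pinball objective is zero; R1 undefined")
        return None
    return 1.0 - fit.objective / null_fit.objective


def qr_aic(fit: QuantileFit) -> float:
    """AIC under the asymmetric-Laplace pseudo-likelihood.

    L = n*(log(tau*(1-tau)) - 1 - log(V/n)), AIC = -2L + 2p.  A perfect fit
    (V = 0) returns -inf as a sentinel.
    """
    if fit.objective <= 0.0:
        return float("-inf")
    tau, n = fit.tau, fit.n
    loglik = n * (np.log(tau * (1.0 - tau)) - 1.0 - np.log(fit.objective / n))
    return float(-2.0 * loglik + 2.0 * fit.p)


def compare_models(
    fits: Sequence[QuantileFit], threshold: float = 25.0
) -> dict:
    """Select among nested fits by the largest drop in AIC.

    ``fits`` are ordered simplest to richest on the same response and tau.
    A richer model is preferred over the current selection only when its AIC
    is smaller by more than ``threshold`` (default 25, a deliberately
    stringent evidence bar for national-scale survey data).
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    n0, tau0 = fits[0].n, fits[0].tau
    for f in fits:
        if f.n != n0 or f.tau != tau0:
            raise ValueError("fits must share the response and tau")
    aics = [qr_aic(f) for f in fits]
    best = 0
    for j in range(1, len(fits)):
        if aics[best] - aics[j] > threshold:
            best = j
    return {
        "selected_index": best,
        "selected": fits[best],
        "aic": aics,
        "delta_aic_vs_selected": [aics[j] - aics[best] for j in range(len(fits))],
        "threshold": threshold,
    }


def bootstrap_fits(
    y: np.ndarray,
    X: np.ndarray,
    tau: float = 0.9,
    n_reps: int = 10_000,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> BootstrapResult:
    """Pairs (site-level) bootstrap of the quantile fit.

    Sites are resampled with replacement and the model refit on each
    replicate; replicates whose resampled design is rank-deficient are
    dropped and counted.  More than 10% dropped replicates is an error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_reps, p))
    dropped = 0
    kept = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        try:
            fit = fit_quantile_regression(yb, Xb, tau=tau, names=names)
        except (ValueError, RuntimeError):
            dropped += 1
            continue
        coefs[kept] = fit.coef
        kept += 1
    if dropped > 0.10 * n_reps:
        raise RuntimeError(
            f"{dropped}/{n_reps} bootstrap replicates had degenerate designs"
        )
    return BootstrapResult(
        coef=coefs[:kept], tau=tau, n_reps=n_reps, n_dropped=dropped,
        seed=seed, names=list(names) if names else [],
    )
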