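"""Linear quantile regression of log stand density, solved as a linear program.

The tau-th conditional-quantile line minimises the asymmetric check loss

    sum_{e_i >= 0} tau * e_i  +  sum_{e_i < 0} (1 - tau) * (-e_i),
    e_i = y_i - x_i' gamma.

Splitting each residual into its positive and negative parts turns this into a
linear program solved exactly (to solver tolerance) with HiGHS; no smoothing
parameter is involved and the optimum interpolates at least p data points,
which is what makes high quantiles (tau 0.90-0.99) usable as self-thinning
boundary estimates.  Confidence intervals are percentile bootstrap over
(x, y)-pair resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog


class QuantileConvergenceError(RuntimeError):
    """The LP solver failed; carries the solver status message."""


def check_loss(residuals: np.ndarray, tau: float) -> float:
    """The asymmetric absolute loss rho_tau summed over residuals."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


@dataclass
class QuantileFit:
    tau: float
    coefficients: np.ndarray  # intercept first
    converged: bool
    objective: float
    ci: np.ndarray | None = None  # (p, 2) percentile bootstrap 95% bounds

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients


def fit_quantile(X: np.ndarray, y: np.ndarray, tau: float) -> QuantileFit:
    """Exact tau-th quantile regression via the split-residual linear program.

    Parameters
    ----------
    X : (n, p) design rows, intercept column first.
    y : (n,) responses.
    tau : quantile level in (0, 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} rows, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient (collinear)")

    # variables: gamma (p, free), u (n, >=0, positive part), w (n, >=0, negative part)
    # minimise tau * 1'u + (1-tau) * 1'w  s.t.  X gamma + u - w = y
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise QuantileConvergenceError(
            f"quantile LP did not converge at tau={tau}: {res.message}"
        )
    gamma = res.x[:p]
    obj = check_loss(y - X @ gamma, tau)
    return QuantileFit(tau=tau, coefficients=gamma, converged=True, objective=obj)


def fit_quantile_path(
    X: np.ndarray,
    y: np.ndarray,
    taus=(0.900, 0.925, 0.950, 0.975, 0.990),
) -> list[QuantileFit]:
    """Fit a path of quantile levels; per-tau failures are recorded, not raised.

    A failed tau yields a QuantileFit with ``converged=False`` and NaN
    coefficients.  Raises only if every tau fails.
    """
    fits = []
    p = np.asarray(X).shape[1]
    for tau in taus:
        try:
            fits.append(fit_quantile(X, y, tau))
        except (QuantileConvergenceError, np.linalg.LinAlgError):
            fits.append(
                QuantileFit(tau=tau, coefficients=np.full(p, np.nan),
                            converged=False, objective=np.nan)
            )
    if not any(f.converged for f in fits):
        raise QuantileConvergenceError("no quantile level converged")
    return fits


def quantile_ci(
    X: np.ndarray,
    y: np.ndarray,
    tau: float,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> np.ndarray:
    """Percentile-bootstrap confidence intervals for the quantile coefficients.

    Resamples (x, y) pairs with replacement; returns a (p, 2) array of lower
    and upper bounds.  Reproducible for a given seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, p))
    b = 0
    attempts = 0
    while b < n_boot and attempts < 3 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        try:
            fit = fit_quantile(X[idx], y[idx], tau)
        except (QuantileConvergenceError, np.linalg.LinAlgError):
            continue  # degenerate resample; redraw
        draws[b] = fit.coefficients
        b += 1
    if b < n_boot:
        raise QuantileConvergenceError("too many degenerate bootstrap resamples")
    lo = (1.0 - level) / 2.0
    return np.quantile(draws, [lo, 1.0 - lo], axis=0).T


def enumerate_pair_lines(x: np.ndarray, y: np.ndarray, tau: float):
    """Brute-force oracle for single-covariate quantile regression.

    The check-loss optimum interpolates at least two data points, so for a
    1-covariate design it suffices to score every line through a pair of
    points.  Returns (best coefficients (2,), best objective).  O(n^3); for
    tests on small instances only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    best_obj = np.inf
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            slope = (y[j] - y[i]) / (x[j] - x[i])
            intercept = y[i] - slope * x[i]
            obj = check_loss(y - (intercept + slope * x), tau)
            if obj < best_obj:
                best_obj = obj
                best = np.array([intercept, slope])
    if best is None:
        raise ValueError("all x identical; no line through pairs exists")
    return best, best_obj
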