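"""Maximum-likelihood stochastic frontier estimation of the self-thinning line.

The boundary is an *upper* frontier on log density: observed ln N equals the
frontier value plus a composed error

    eps = v - u,   v ~ N(0, sigma_v^2),   u >= 0,

so the symmetric component v scatters plots around the line while the
one-sided component u (how far a stand sits below its maximum carrying
capacity) pulls them down.  Three laws for u are supported and compared:

* NH  normal-half-normal:      u = |N(0, sigma_u^2)|
* NE  normal-exponential:      u ~ Exp(scale sigma_u), sigma_u^2 the squared scale
* NT  normal-truncated-normal: u = N(mu, sigma_u^2) truncated to u >= 0

The NH and NE marginal densities of eps are the classical closed forms of the
frontier literature; NT is the Stevenson generalisation with pre-truncation
mean mu (NH is NT at mu = 0).  Estimation maximises the sample log-likelihood
over (coefficients, log-variances[, mu]) with multi-start quasi-Newton
optimisation; standard errors come from the observed information
(finite-difference Hessian, delta method back to the variance scale).
The conditional mean E[u | eps] (Jondrow-type) predicts each plot's distance
below the frontier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.stats import norm

from .density_models import RM, VDM, ThinningModelSpec

logger = logging.getLogger(__name__)

NH = "NH"
NE = "NE"
NT = "NT"
_DISTS = (NH, NE, NT)


class SFAConvergenceError(RuntimeError):
    """No optimisation start converged; carries the per-start trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class ComposedErrorSpec:
    """Distributional parameters of the composed error eps = v - u."""

    dist: str
    sigma_v2: float
    sigma_u2: float
    mu: float = 0.0

    def __post_init__(self):
        if self.dist not in _DISTS:
            raise ValueError(f"dist must be one of {_DISTS}, got {self.dist!r}")
        if self.sigma_v2 <= 0:
            raise ValueError("sigma_v2 must be > 0")
        if self.sigma_u2 < 0:
            raise ValueError("sigma_u2 must be >= 0")
        if self.dist != NT and self.mu != 0.0:
            raise ValueError("mu is only free for the NT distribution")


def composed_error_logdensity(error: ComposedErrorSpec, eps) -> np.ndarray:
    """Log marginal density of eps = v - u for the given composed-error law.

    NH: ln[(2/sigma) phi(eps/sigma) Phi(-eps*lambda/sigma)], sigma^2 = sv2+su2,
    lambda = su/sv.  NE: ln[(1/su) exp(eps/su + sv2/(2 su^2)) Phi(-eps/sv - sv/su)]
    with su the exponential scale.  NT: (1/sigma) phi((eps+mu)/sigma) *
    Phi(mu*/sigma*) / Phi(mu/su) with mu* = (sv2*mu - su2*eps)/sigma^2 and
    sigma* = su*sv/sigma.  All evaluated in log space with stable log-Phi.
    """
    eps = np.asarray(eps, dtype=float)
    sv2, su2 = error.sigma_v2, error.sigma_u2
    sv = math.sqrt(sv2)
    if su2 == 0.0:
        # u degenerates: at a point mass max(mu, 0) for NT, 0 otherwise
        shift = max(error.mu, 0.0) if error.dist == NT else 0.0
        return norm.logpdf(eps + shift, scale=sv)
    su = math.sqrt(su2)

    if error.dist == NE:
        return (
            -math.log(su)
            + eps / su
            + sv2 / (2.0 * su2)
            + norm.logcdf(-eps / sv - sv / su)
        )

    mu = error.mu if error.dist == NT else 0.0
    s2 = sv2 + su2
    s = math.sqrt(s2)
    sigma_star = su * sv / s
    mu_star = (sv2 * mu - su2 * eps) / s2
    out = (
        norm.logpdf((eps + mu) / s)
        - math.log(s)
        + norm.logcdf(mu_star / sigma_star)
        - norm.logcdf(mu / su)
    )
    return out


def sample_composed_error(
    error: ComposedErrorSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw eps = v - u; the Monte-Carlo counterpart of the closed-form density."""
    v = rng.normal(0.0, math.sqrt(error.sigma_v2), size)
    su = math.sqrt(error.sigma_u2)
    if error.sigma_u2 == 0.0:
        u = np.full(size, max(error.mu, 0.0) if error.dist == NT else 0.0)
    elif error.dist == NE:
        u = rng.exponential(su, size)
    elif error.dist == NH:
        u = np.abs(rng.normal(0.0, su, size))
    else:
        a = (0.0 - error.mu) / su
        u = stats.truncnorm.rvs(a, np.inf, loc=error.mu, scale=su,
                                size=size, random_state=rng)
    return v - u


@dataclass
class SFAFit:
    """A converged stochastic frontier fit."""

    spec: ThinningModelSpec
    error: ComposedErrorSpec
    loglik: float
    aic: float
    se: np.ndarray  # (coefficients..., sigma_v2, sigma_u2[, mu]) order
    converged: bool
    n_obs: int
    boundary_sigma_u: bool = False  # sigma_u2 ~ 0: frontier ~ OLS

    @property
    def n_params(self) -> int:
        return len(self.spec.coefficients) + 2 + (1 if self.error.dist == NT else 0)

    @property
    def coef_se(self) -> np.ndarray:
        return self.se[: len(self.spec.coefficients)]


def _unpack(theta: np.ndarray, p: int, dist: str) -> tuple[np.ndarray, ComposedErrorSpec]:
    beta = theta[:p]
    sv2 = math.exp(theta[p])
    su2 = math.exp(theta[p + 1])
    mu = theta[p + 2] if dist == NT else 0.0
    return beta, ComposedErrorSpec(dist=dist, sigma_v2=sv2, sigma_u2=su2, mu=mu)


def _negloglik(theta, X, y, dist):
    p = X.shape[1]
    beta, err = _unpack(theta, p, dist)
    ll = composed_error_logdensity(err, y - X @ beta)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.sum(ll))


def _ols_start(X, y, dist):
    """Corrected-OLS starting point: split the residual variance evenly and
    shift the intercept up by the implied mean of u."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = max(float(np.var(resid)), 1e-4)
    sv2 = su2 = s2 / 2.0
    su = math.sqrt(su2)
    mean_u = su * math.sqrt(2.0 / math.pi) if dist in (NH, NT) else su
    start = beta.copy()
    start[0] += mean_u
    theta = np.concatenate([start, [math.log(sv2), math.log(su2)]])
    if dist == NT:
        theta = np.concatenate([theta, [0.0]])
    return theta


def _opg_information(theta, X, y, dist, h=1e-5):
    """Outer-product-of-gradients (BHHH) estimate of the information matrix.

    Per-observation scores by central differences in the working space.  More
    robust than the Hessian when a variance component sits near its boundary,
    where the local quadratic underestimates the spread of the estimator.
    """
    p = X.shape[1]

    def ll_vec(t):
        beta, err = _unpack(t, p, dist)
        return composed_error_logdensity(err, y - X @ beta)

    k = len(theta)
    g = np.empty((len(y), k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        g[:, j] = (ll_vec(theta + e) - ll_vec(theta - e)) / (2.0 * h)
    return g.T @ g


def _num_hessian(fun, theta, h=1e-4):
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


def fit_sfa(
    X: np.ndarray,
    y: np.ndarray,
    dist: str = NT,
    starts: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
    form: str | None = None,
) -> SFAFit:
    """Fit the stochastic frontier by maximum likelihood.

    Parameters
    ----------
    X, y : design matrix (intercept column first) and ln N responses.
    dist : composed-error law, 'NH', 'NE' or 'NT'.
    starts : optional explicit starting vector(s) in the working
        parameterisation (beta..., ln sigma_v2, ln sigma_u2[, mu]); by default
        a corrected-OLS start plus ``n_starts - 1`` jittered replicas.
    seed : sub-seed for the start jitter (estimation itself is deterministic).
    form : 'RM' or 'VDM'; inferred from the column count when omitted.

    Notes
    -----
    Optimisation is over log-variances so the variance positivity constraint
    is implicit; bounds keep mu in [-5, 5] and log-variances in [-8, 5].  The
    best converged optimum across starts is returned; an estimate with
    sigma_u2 effectively zero is flagged (``boundary_sigma_u``), since there
    the frontier is indistinguishable from mean regression.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if dist not in _DISTS:
        raise ValueError(f"dist must be one of {_DISTS}")
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} rows, got {n}")
    if form is None:
        form = RM if p == 2 else VDM
    k_extra = 3 if dist == NT else 2
    n_theta = p + k_extra

    base = _ols_start(X, y, dist)
    if starts is not None:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
    else:
        rng = np.random.default_rng(seed)
        jitters = [base]
        for _ in range(max(n_starts - 1, 0)):
            t = base.copy()
            t[:p] += rng.normal(0.0, 0.1 * np.abs(base[:p]) + 0.05)
            t[p:p + 2] += rng.normal(0.0, 0.5, 2)
            if dist == NT:
                t[p + 2] += rng.normal(0.0, 0.3)
            jitters.append(t)
        starts = np.array(jitters)

    bounds = [(None, None)] * p + [(-8.0, 5.0), (-8.0, 5.0)]
    if dist == NT:
        bounds.append((-5.0, 5.0))

    best = None
    trace = []
    for s0 in starts:
        res = optimize.minimize(
            _negloglik, s0, args=(X, y, dist), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        trace.append({"start": s0.tolist(), "fun": float(res.fun),
                      "success": bool(res.success), "message": str(res.message)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise SFAConvergenceError(
            f"stochastic frontier ({dist}) failed to converge from all starts",
            trace,
        )

    theta = best.x
    beta, err = _unpack(theta, p, dist)
    loglik = -float(best.fun)
    aic = 2.0 * n_theta - 2.0 * loglik

    # information estimate in the working space, delta method back to
    # (beta, sigma_v2, sigma_u2[, mu]); BHHH first, Hessian as fallback
    se = np.full(n_theta, np.nan)
    jac = np.ones(n_theta)
    jac[p] = err.sigma_v2      # d sigma_v2 / d ln sigma_v2
    jac[p + 1] = err.sigma_u2
    for info in (
        lambda: _opg_information(theta, X, y, dist),
        lambda: _num_hessian(lambda t: _negloglik(t, X, y, dist), theta),
    ):
        try:
            cov = np.linalg.inv(info()) * np.outer(jac, jac)
        except np.linalg.LinAlgError:
            continue
        d = np.diag(cov)
        if np.all(d > 0):
            se = np.sqrt(d)
            break
    if np.any(np.isnan(se)):
        logger.warning("information matrix not positive definite; SEs unavailable")

    spec = ThinningModelSpec(
        form=form,
        intercept_k=float(beta[0]),
        slope_d_alpha=float(beta[1]),
        slope_h_beta=float(beta[2]) if form == VDM else 0.0,
    )
    boundary = err.sigma_u2 < 1e-3
    if boundary:
        logger.warning(
            "sigma_u2 estimate at boundary (%.2e): frontier ~ OLS", err.sigma_u2
        )
    return SFAFit(
        spec=spec, error=err, loglik=loglik, aic=aic, se=se,
        converged=True, n_obs=n, boundary_sigma_u=boundary,
    )


def compare_models(fit_rm: SFAFit, fit_vdm: SFAFit) -> dict:
    """Likelihood-ratio test and AIC difference between the nested RM and VDM fits.

    RM (beta = 0 on ln Hd) is nested in VDM, so the LRT statistic
    2*(ll_VDM - ll_RM) is chi-square with 1 df under the null.
    """
    if fit_rm.error.dist != fit_vdm.error.dist:
        raise ValueError("fits must use the same composed-error distribution")
    if fit_rm.n_obs != fit_vdm.n_obs:
        raise ValueError("fits must be on the same data (n_obs mismatch)")
    stat = 2.0 * (fit_vdm.loglik - fit_rm.loglik)
    stat = max(stat, 0.0)  # guard optimizer tolerance
    return {
        "delta_aic": fit_vdm.aic - fit_rm.aic,
        "lrt_stat": stat,
        "lrt_p": float(stats.chi2.sf(stat, df=1)),
        "df": 1,
    }


def expected_inefficiency(fit: SFAFit, eps) -> np.ndarray:
    """Conditional mean E[u | eps]: each plot's expected shortfall below the frontier.

    Jondrow-type predictor for the fitted law; always >= 0 and increasing as
    eps becomes more negative.
    """
    if not fit.converged:
        raise RuntimeError("fit did not converge")
    err = fit.error
    eps = np.asarray(eps, dtype=float)
    sv2, su2 = err.sigma_v2, err.sigma_u2
    sv = math.sqrt(sv2)
    if su2 == 0.0:
        out = np.zeros_like(eps)
        return out if out.ndim else float(out)
    su = math.sqrt(su2)
    if err.dist == NE:
        mu_t = -eps - sv2 / su
        z = mu_t / sv
        out = mu_t + sv * np.exp(norm.logpdf(z) - norm.logcdf(z))
    else:
        mu = err.mu if err.dist == NT else 0.0
        s2 = sv2 + su2
        sigma_star = su * sv / math.sqrt(s2)
        mu_star = (sv2 * mu - su2 * eps) / s2
        z = mu_star / sigma_star
        out = mu_star + sigma_star * np.exp(norm.logpdf(z) - norm.logcdf(z))
    out = np.maximum(out, 0.0)
    return out if np.ndim(eps) else float(out)
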