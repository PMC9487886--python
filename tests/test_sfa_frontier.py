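"""Composed-error densities, frontier ML, model comparison and inefficiency prediction."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

import selfthin as st
from selfthin import (
    ComposedErrorSpec, compare_models, composed_error_logdensity,
    expected_inefficiency, fit_sfa, sample_composed_error,
)
from selfthin.sfa_frontier import SFAFit
from selfthin.density_models import ThinningModelSpec, VDM, design_matrix

SPECS = [
    ComposedErrorSpec("NH", sigma_v2=0.301, sigma_u2=0.378),
    ComposedErrorSpec("NE", sigma_v2=0.301, sigma_u2=0.378),
    ComposedErrorSpec("NT", sigma_v2=0.301, sigma_u2=0.378, mu=0.4),
    ComposedErrorSpec("NT", sigma_v2=0.2, sigma_u2=0.5, mu=-0.6),
]


class TestComposedErrorDensity:
    @pytest.mark.parametrize("err", SPECS, ids=lambda e: f"{e.dist}-mu{e.mu}")
    def test_integrates_to_one(self, err):
        val, abserr = integrate.quad(
            lambda e: math.exp(composed_error_logdensity(err, e)), -15, 15,
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_half_normal_limit_to_pure_noise(self):
        # sigma_u2 -> 0 recovers the symmetric normal density pointwise
        eps = np.linspace(-2, 2, 41)
        err_small = ComposedErrorSpec("NH", 0.3, 1e-12)
        np.testing.assert_allclose(
            composed_error_logdensity(err_small, eps),
            norm.logpdf(eps, scale=math.sqrt(0.3)),
            atol=1e-4,
        )
        err_zero = ComposedErrorSpec("NH", 0.3, 0.0)
        np.testing.assert_allclose(
            composed_error_logdensity(err_zero, eps),
            norm.logpdf(eps, scale=math.sqrt(0.3)),
        )

    def test_left_skew_relative_to_symmetric_normal(self):
        err = ComposedErrorSpec("NH", 0.301, 0.378)
        total_sd = math.sqrt(0.301 + 0.378)
        eps = 2.0  # far into the upper tail
        assert composed_error_logdensity(err, eps) < norm.logpdf(eps, scale=total_sd)

    @pytest.mark.parametrize("err", SPECS[:3], ids=lambda e: e.dist)
    def test_matches_monte_carlo_histogram(self, err):
        rng = np.random.default_rng(99)
        draws = sample_composed_error(err, 10**6, rng)
        edges = np.arange(-4.0, 2.0, 0.1)
        hist, _ = np.histogram(draws, bins=edges, density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        dens = np.exp(composed_error_logdensity(err, centers))
        assert np.max(np.abs(hist - dens)) < 0.01

    def test_invalid_sigma_v_rejected(self):
        with pytest.raises(ValueError):
            ComposedErrorSpec("NH", sigma_v2=0.0, sigma_u2=0.1)


_GEN_DIST = {"NH": "half_normal", "NE": "exponential", "NT": "truncated_normal"}


def _sim_xy(n, rng, k=8.424, alpha=-0.996, beta=0.621, sv2=0.301, su2=0.378,
            dist="NH"):
    cfg = st.SyntheticConfig(k=k, alpha=alpha, beta=beta, sigma_v2=sv2,
                             sigma_u2=su2, dist=_GEN_DIST[dist], n_plots=n,
                             seed=int(rng.integers(2**31)))
    pairs, _ = st.simulate_stands(cfg)
    return design_matrix([p.t0 for p in pairs], VDM)


class TestFitSFA:
    def test_no_inefficiency_matches_ols(self):
        rng = np.random.default_rng(17)
        X, y = _sim_xy(2000, rng, su2=0.0)
        fit = fit_sfa(X, y, dist="NH", seed=0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_se = np.sqrt(np.diag(
            np.linalg.inv(X.T @ X) * np.var(y - X @ ols, ddof=X.shape[1])
        ))
        assert fit.boundary_sigma_u or fit.error.sigma_u2 < 0.05
        # slopes agree with OLS well within sampling error
        np.testing.assert_allclose(fit.spec.coefficients[1:], ols[1:],
                                   atol=3 * np.max(ols_se[1:]))

    def test_recovers_truth_at_large_n(self):
        rng = np.random.default_rng(23)
        X, y = _sim_xy(4000, rng)
        fit = fit_sfa(X, y, dist="NH", seed=0)
        np.testing.assert_allclose(
            fit.spec.coefficients, [8.424, -0.996, 0.621], atol=0.25
        )
        assert fit.error.sigma_v2 == pytest.approx(0.301, abs=0.08)
        assert fit.error.sigma_u2 == pytest.approx(0.378, abs=0.12)

    def test_aic_identity_and_param_count(self):
        rng = np.random.default_rng(5)
        X, y = _sim_xy(185, rng)
        for dist, k_extra in (("NH", 2), ("NE", 2), ("NT", 3)):
            fit = fit_sfa(X, y, dist=dist, seed=0)
            assert fit.n_params == 3 + k_extra
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_beats_ols_start_loglik(self):
        from selfthin.sfa_frontier import _negloglik, _ols_start

        rng = np.random.default_rng(31)
        X, y = _sim_xy(185, rng)
        fit = fit_sfa(X, y, dist="NH", seed=0)
        assert fit.loglik >= -_negloglik(_ols_start(X, y, "NH"), X, y, "NH") - 1e-6

    def test_explicit_start_reproduces_optimum(self):
        from selfthin.sfa_frontier import _ols_start

        rng = np.random.default_rng(37)
        X, y = _sim_xy(185, rng)
        a = fit_sfa(X, y, dist="NH", seed=0)
        b = fit_sfa(X, y, dist="NH", starts=_ols_start(X, y, "NH"))
        assert b.loglik == pytest.approx(a.loglik, abs=1e-4)
        np.testing.assert_allclose(a.spec.coefficients, b.spec.coefficients, atol=0.02)

    def test_too_few_rows_rejected(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            fit_sfa(X, np.ones(4), dist="NH")


class TestCompareModels:
    def test_identical_fits_give_null_result(self):
        rng = np.random.default_rng(41)
        X, y = _sim_xy(185, rng)
        fit = fit_sfa(X, y, dist="NH", seed=0)
        res = compare_models(fit, fit)
        assert res["lrt_stat"] == 0.0 and res["lrt_p"] == 1.0

    def test_mismatched_dist_rejected(self):
        rng = np.random.default_rng(43)
        X, y = _sim_xy(185, rng)
        a = fit_sfa(X, y, dist="NH", seed=0)
        b = fit_sfa(X, y, dist="NE", seed=0)
        with pytest.raises(ValueError):
            compare_models(a, b)


class TestExpectedInefficiency:
    def _fit(self, dist="NH", mu=0.0):
        spec = ThinningModelSpec(VDM, 8.4, -1.0, 0.6)
        err = ComposedErrorSpec(dist, 0.301, 0.378, mu if dist == "NT" else 0.0)
        return SFAFit(spec=spec, error=err, loglik=0.0, aic=0.0,
                      se=np.zeros(6), converged=True, n_obs=100)

    def test_zero_inefficiency_variance_gives_zero(self):
        spec = ThinningModelSpec(VDM, 8.4, -1.0, 0.6)
        fit = SFAFit(spec=spec, error=ComposedErrorSpec("NH", 0.3, 0.0),
                     loglik=0.0, aic=0.0, se=np.zeros(5), converged=True, n_obs=10)
        assert np.all(expected_inefficiency(fit, np.linspace(-2, 2, 9)) == 0.0)

    @pytest.mark.parametrize("dist", ["NH", "NE", "NT"])
    def test_monotone_decreasing_in_eps(self, dist):
        fit = self._fit(dist, mu=0.3)
        vals = expected_inefficiency(fit, np.linspace(-3, 3, 61))
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals >= 0)

    @pytest.mark.parametrize("dist", ["NH", "NE", "NT"])
    def test_matches_monte_carlo_conditional_mean(self, dist):
        fit = self._fit(dist, mu=0.3)
        rng = np.random.default_rng(55)
        err = fit.error
        v = rng.normal(0, math.sqrt(err.sigma_v2), 10**6)
        su = math.sqrt(err.sigma_u2)
        if dist == "NH":
            u = np.abs(rng.normal(0, su, 10**6))
        elif dist == "NE":
            u = rng.exponential(su, 10**6)
        else:
            from scipy.stats import truncnorm

            u = truncnorm.rvs(-err.mu / su, np.inf, loc=err.mu, scale=su,
                              size=10**6, random_state=rng)
        eps = v - u
        for center in (-1.0, -0.5, 0.0):
            sel = np.abs(eps - center) < 0.025
            mc = u[sel].mean()
            pred = expected_inefficiency(fit, center)
            assert pred == pytest.approx(mc, rel=0.02)
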