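"""Traditional boundary-point selection rules and the OLS boundary fit."""

import math

import numpy as np
import pytest

import selfthin as st
from selfthin import (
    RM, VDM, SelectionError, ThinningModelSpec, fit_ols_boundary,
    select_interval, select_mortality, select_relative_density, select_upper_hull,
)
from selfthin.boundary_selection import SelectionResult

from .conftest import make_pair, make_plot


def _scatter(rng, n=60, contaminated=True):
    """Frontier scatter: points on/below ln N = 11 - 1.6 ln D, plus a cloud of
    clearly-understocked small-diameter plots (young stands not yet thinning)
    that flattens a naive all-data OLS line."""
    d = rng.uniform(7, 23, n)
    u = rng.exponential(0.15, n)
    if contaminated:
        p_under = 0.7 * (1.0 - (d - 7.0) / 16.0)
        u = np.where(rng.uniform(size=n) < p_under, u + rng.uniform(0.4, 1.2, n), u)
    ln_n = 11.0 - 1.6 * np.log(d) - u
    return [
        make_plot(plot_id=f"s{i}", tph=math.exp(ln_n[i]), qmd_cm=float(d[i]))
        for i in range(n)
    ]


class TestIntervalSelection:
    def test_bin_maxima_selected(self):
        plots = [
            make_plot("a", tph=1000, qmd_cm=8.0),
            make_plot("b", tph=2000, qmd_cm=8.5),
            make_plot("c", tph=500, qmd_cm=20.0),
            make_plot("d", tph=700, qmd_cm=21.0),
        ]
        sel = select_interval(plots, n_bins=2)
        assert set(sel.selected_ids) == {"b", "d"}

    def test_identical_diameters_fail(self):
        plots = [make_plot(f"p{i}", qmd_cm=10.0) for i in range(5)]
        with pytest.raises(SelectionError):
            select_interval(plots)

    def test_less_biased_slope_than_all_data_ols(self, rng):
        # understocked plots flatten the all-data OLS line; bin maxima resist
        bias_sel, bias_all = [], []
        for r in range(40):
            rng_r = np.random.default_rng(900 + r)
            plots = _scatter(rng_r)
            sel = select_interval(plots, n_bins=8)
            fit_sel = fit_ols_boundary(sel, RM)
            all_fit = fit_ols_boundary(
                SelectionResult("all", [p.plot_id for p in plots], {}, list(plots)),
                RM,
            )
            bias_sel.append(abs(fit_sel.slope_d_alpha - (-1.6)))
            bias_all.append(abs(all_fit.slope_d_alpha - (-1.6)))
        assert np.mean(bias_sel) < np.mean(bias_all)


class TestMortalitySelection:
    def test_threshold_zero_keeps_all_and_above_one_keeps_none(self):
        pairs = [make_pair(f"p{i}", n_dead=10 * i) for i in range(4)]
        assert len(select_mortality(pairs, threshold=0.0).selected_ids) == 4
        assert len(select_mortality(pairs, threshold=1.01).selected_ids) == 0

    def test_default_threshold_on_study_conditions(self, default_pairs):
        pairs, _ = default_pairs
        sel = select_mortality(pairs, threshold=0.20)
        # mean mortality ~35%: the majority of plots passes the 20% rule
        assert len(sel.selected_ids) > len(pairs) / 2


class TestRelativeDensitySelection:
    SPEC = ThinningModelSpec(RM, 11.0, -1.6)

    def test_standard_zero_keeps_all(self):
        plots = _scatter(np.random.default_rng(1))
        sel = select_relative_density(plots, self.SPEC, standard=0.0)
        assert len(sel.selected_ids) == len(plots)

    def test_all_below_line_keeps_none(self):
        plots = [make_plot(f"p{i}", tph=100.0, qmd_cm=10 + i) for i in range(5)]
        sel = select_relative_density(plots, self.SPEC, standard=1.0)
        assert sel.selected_ids == []

    def test_selected_subset_line_sits_above_all_data_line(self, rng):
        plots = _scatter(rng, n=80)
        all_sel = SelectionResult("all", [p.plot_id for p in plots], {}, list(plots))
        base = fit_ols_boundary(all_sel, RM)
        sel = select_relative_density(plots, base, standard=1.0)
        upper = fit_ols_boundary(sel, RM)
        mean_ln_d = np.mean([math.log(p.qmd_cm) for p in plots])
        assert (upper.intercept_k + upper.slope_d_alpha * mean_ln_d
                > base.intercept_k + base.slope_d_alpha * mean_ln_d)

    def test_unfitted_spec_rejected(self):
        with pytest.raises(RuntimeError):
            select_relative_density([make_plot()], ThinningModelSpec.unfitted(RM))


class TestUpperHull:
    def test_triangle_upper_vertices(self):
        plots = [
            make_plot("lo", tph=100.0, qmd_cm=8.0),
            make_plot("hi", tph=3000.0, qmd_cm=12.0),
            make_plot("rt", tph=150.0, qmd_cm=20.0),
        ]
        sel = select_upper_hull(plots)
        assert set(sel.selected_ids) == {"lo", "hi", "rt"}
        # an interior point below the hull changes nothing
        plots2 = plots + [make_plot("in", tph=120.0, qmd_cm=12.0)]
        assert set(select_upper_hull(plots2).selected_ids) == set(sel.selected_ids)

    def test_collinear_points_all_returned(self):
        plots = [
            make_plot(f"p{i}", tph=math.exp(10 - 1.5 * math.log(d)), qmd_cm=d)
            for i, d in enumerate((8.0, 12.0, 18.0))
        ]
        assert len(select_upper_hull(plots).selected_ids) == 3

    def test_no_point_above_hull_chords(self, rng):
        plots = _scatter(rng, n=50)
        sel = select_upper_hull(plots)
        x = np.log([p.qmd_cm for p in sel.plots])
        y = np.log([p.tph for p in sel.plots])
        order = np.argsort(x)
        x, y = x[order], y[order]
        for p in plots:
            px, py = math.log(p.qmd_cm), math.log(p.tph)
            j = np.searchsorted(x, px)
            if 0 < j < len(x):
                t = (px - x[j - 1]) / (x[j] - x[j - 1])
                chord = y[j - 1] + t * (y[j] - y[j - 1])
                assert py <= chord + 1e-9

    def test_duplicate_diameters_fall_back_to_densest(self):
        plots = [
            make_plot("a", tph=100.0, qmd_cm=10.0),
            make_plot("b", tph=900.0, qmd_cm=10.0),
            make_plot("c", tph=500.0, qmd_cm=15.0),
            make_plot("d", tph=200.0, qmd_cm=20.0),
        ]
        sel = select_upper_hull(plots)
        assert "a" not in sel.selected_ids and "b" in sel.selected_ids


class TestOLSBoundaryFit:
    def test_noiseless_frontier_recovered_exactly(self):
        cfg = st.SyntheticConfig(sigma_v2=0.0, sigma_u2=0.0, n_plots=30, seed=2)
        pairs, _ = st.simulate_stands(cfg)
        plots = [p.t0 for p in pairs]
        sel = SelectionResult("all", [p.plot_id for p in plots], {}, plots)
        spec = fit_ols_boundary(sel, VDM)
        assert spec.intercept_k == pytest.approx(cfg.k, abs=1e-8)
        assert spec.slope_d_alpha == pytest.approx(cfg.alpha, abs=1e-8)
        assert spec.slope_h_beta == pytest.approx(cfg.beta, abs=1e-8)

    def test_matches_normal_equation_oracle(self):
        plots = [
            make_plot(f"p{i}", tph=t, qmd_cm=d)
            for i, (t, d) in enumerate([(2000, 7), (1500, 9), (1100, 12),
                                        (800, 16), (600, 21)])
        ]
        sel = SelectionResult("all", [p.plot_id for p in plots], {}, plots)
        spec = fit_ols_boundary(sel, RM)
        X = np.column_stack([np.ones(5), np.log([p.qmd_cm for p in plots])])
        y = np.log([p.tph for p in plots])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose([spec.intercept_k, spec.slope_d_alpha],
                                   oracle, atol=1e-10)

    def test_interval_selection_steeper_than_all_data(self, rng):
        steeper = 0
        for r in range(30):
            rng_r = np.random.default_rng(1700 + r)
            plots = _scatter(rng_r)
            sel_fit = fit_ols_boundary(select_interval(plots, n_bins=8), RM)
            all_fit = fit_ols_boundary(
                SelectionResult("all", [p.plot_id for p in plots], {}, list(plots)), RM
            )
            steeper += sel_fit.slope_d_alpha < all_fit.slope_d_alpha
        assert steeper >= 20  # understocked cloud flattens the all-data slope

    def test_too_few_points_rejected(self):
        sel = SelectionResult("x", ["a"], {}, [make_plot()])
        with pytest.raises(SelectionError):
            fit_ols_boundary(sel, RM)


class TestIdempotence:
    def test_selection_rules_idempotent(self, rng):
        plots = _scatter(rng, n=40)
        hull = select_upper_hull(plots)
        again = select_upper_hull(hull.plots)
        assert set(again.selected_ids) == set(hull.selected_ids)
        spec = ThinningModelSpec(RM, 11.0, -1.6)
        rd = select_relative_density(plots, spec, standard=0.8)
        assert set(select_relative_density(rd.plots, spec, standard=0.8).selected_ids) \
            == set(rd.selected_ids)
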