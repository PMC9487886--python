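"""Traditional boundary-point selection for OLS self-thinning fits.

Before quantile or frontier estimators, self-thinning lines were fitted by
ordinary least squares on a hand-picked subset of "boundary" plots.  Four
selection rules are implemented: equal-width ln D interval maxima, a period
mortality threshold (classically 20%), a relative-density standard against a
provisional line, and an upper convex hull in (ln D, ln N) — the latter an
objective surrogate for the subjective visual method, and labelled as such in
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density_models import RM, VDM, ThinningModelSpec, design_matrix, relative_density
from .stand_data import PlotPair, PlotRecord, compute_mortality


class SelectionError(ValueError):
    """The selection rule cannot produce a usable subset."""


@dataclass
class SelectionResult:
    method: str
    selected_ids: list[str]
    params: dict
    plots: list[PlotRecord] = field(repr=False, default_factory=list)
    boundary_fit: ThinningModelSpec | None = None


def select_interval(
    plots: Sequence[PlotRecord], n_bins: int = 10, points_per_bin: int = 1
) -> SelectionResult:
    """Keep the densest plot(s) within each equal-width bin of ln D.

    Ties on density break by plot id.  Bins are equal-width over the observed
    ln D range; empty bins contribute nothing.
    """
    if n_bins < 2:
        raise SelectionError("n_bins must be >= 2")
    ln_d = np.log([p.qmd_cm for p in plots])
    lo, hi = float(ln_d.min()), float(ln_d.max())
    if lo == hi:
        raise SelectionError("all plots share one ln D value: fewer than 2 bins occupied")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(ln_d, edges[1:-1]), 0, n_bins - 1)
    if len(set(which.tolist())) < 2:
        raise SelectionError("fewer than 2 non-empty ln D bins")
    selected: list[PlotRecord] = []
    for b in range(n_bins):
        members = [p for p, w in zip(plots, which) if w == b]
        members.sort(key=lambda p: (-p.tph, p.plot_id))
        selected.extend(members[:points_per_bin])
    return SelectionResult(
        method="interval",
        selected_ids=[p.plot_id for p in selected],
        params={"n_bins": n_bins, "points_per_bin": points_per_bin},
        plots=selected,
    )


def select_mortality(pairs: Sequence[PlotPair], threshold: float = 0.20) -> SelectionResult:
    """Keep plots whose period mortality reaches the threshold (default 20%).

    The 20% convention comes from plantation studies; in mixed stands much
    mortality is light/space-driven rather than density-driven, so the
    threshold is exposed for adjustment.
    """
    selected = [p.t0 for p in pairs if compute_mortality(p) >= threshold]
    return SelectionResult(
        method="mortality",
        selected_ids=[p.plot_id for p in selected],
        params={"threshold": threshold},
        plots=selected,
    )


def select_relative_density(
    plots: Sequence[PlotRecord], spec: ThinningModelSpec, standard: float = 1.0
) -> SelectionResult:
    """Keep plots at or above a relative-density standard versus a provisional line.

    The provisional spec is typically a mean OLS line; standard 1.0 keeps
    plots on or above it.
    """
    if not spec.is_fitted:
        raise RuntimeError("provisional spec is unfitted")
    selected = [p for p in plots if relative_density(p, spec) >= standard]
    return SelectionResult(
        method="relative_density",
        selected_ids=[p.plot_id for p in selected],
        params={"standard": standard},
        plots=selected,
    )


def _upper_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Andrew's monotone chain, upper hull only; collinear points are kept."""
    order = np.lexsort((y, x))
    hull: list[int] = []
    for i in order:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            tol = 1e-10 * max(abs(x[i] - x[o]), 1.0) * max(abs(y[i] - y[o]), 1.0)
            if cross > tol:  # left turn: a lies below the chord o->i
                hull.pop()
            else:
                break
        hull.append(i)
    return sorted(hull)


def select_upper_hull(
    plots: Sequence[PlotRecord], drop_endpoints: bool = False
) -> SelectionResult:
    """Upper convex hull vertices in (ln D, ln N): the objective stand-in for
    visually tracing the scatter's upper edge.

    With ``drop_endpoints`` the two extreme-ln D vertices are excluded (they
    often reflect range truncation rather than the thinning boundary).  Exactly
    collinear scatters return all points; duplicate ln D values fall back to
    the densest plot per distinct diameter.
    """
    if len(plots) < 3:
        raise SelectionError("need at least 3 plots for a hull")
    x = np.log([p.qmd_cm for p in plots])
    y = np.log([p.tph for p in plots])
    if len(np.unique(x)) < len(x):
        keep = {}
        for i, (xi, yi) in enumerate(zip(x, y)):
            if xi not in keep or y[keep[xi]] < yi:
                keep[xi] = i
        idx_pool = sorted(keep.values())
        x, y = x[idx_pool], y[idx_pool]
        pool = [plots[i] for i in idx_pool]
    else:
        pool = list(plots)
    if len(pool) < 2:
        raise SelectionError("degenerate input: a single distinct ln D value")
    idx = _upper_hull_indices(x, y)
    if drop_endpoints and len(idx) > 2:
        xmin, xmax = x[idx].min(), x[idx].max()
        idx = [i for i in idx if x[i] not in (xmin, xmax)] or idx
    selected = [pool[i] for i in idx]
    return SelectionResult(
        method="upper_hull",
        selected_ids=[p.plot_id for p in selected],
        params={"drop_endpoints": drop_endpoints, "note": "surrogate for the visual method"},
        plots=selected,
    )


def fit_ols_boundary(selection: SelectionResult, form: str = RM) -> ThinningModelSpec:
    """OLS of ln N on ln D (and ln Hd for VDM) over the selected subset.

    The classical final step of the traditional methods; stores the fitted
    spec on the selection result as well as returning it.
    """
    plots = selection.plots
    p = 2 if form == RM else 3
    if len(plots) < p:
        raise SelectionError(
            f"{selection.method}: need >= {p} selected plots, got {len(plots)}"
        )
    X, y = design_matrix(plots, form)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("selected subset gives a rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    spec = ThinningModelSpec(
        form=form,
        intercept_k=float(beta[0]),
        slope_d_alpha=float(beta[1]),
        slope_h_beta=float(beta[2]) if form == VDM else 0.0,
    )
    selection.boundary_fit = spec
    return spec
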