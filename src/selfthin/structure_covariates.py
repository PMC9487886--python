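"""Stand structure and topographic covariates of maximum density.

Per-plot metrics: Shannon H' and Simpson DS diversity from species tallies,
coefficient of variation of stem DBH, and the slenderness ratio Hd/D
(dominant height in m over mean DBH in m).  A least-squares covariate model
relates projected maximum density (SDI) to altitude, Simpson index and Hd/D,
reporting its relative error against the mean observed SDI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stand_data import PlotRecord


@dataclass
class StructureMetrics:
    shannon: float
    simpson: float
    cv_dbh: float | None
    hd_over_d: float


@dataclass
class CovariateModelFit:
    form: str
    coefficients: np.ndarray
    names: list[str]
    residual_sd: float
    relative_error_pct: float
    r2: float


def shannon_index(counts: Mapping[str, int]) -> float:
    """Shannon diversity H' = -sum p_i ln p_i over species with stems present."""
    vals = np.array([c for c in counts.values() if c > 0], dtype=float)
    if vals.size == 0 or vals.sum() <= 0:
        raise ValueError("empty species tally")
    p = vals / vals.sum()
    return float(-np.sum(p * np.log(p)))


def simpson_index(counts: Mapping[str, int]) -> float:
    """Simpson diversity DS = 1 - sum n_i(n_i - 1) / (N(N - 1)).

    One minus the probability that two stems drawn without replacement are
    conspecific; 0 for a monoculture, approaching 1 for many even species.
    """
    vals = np.array([c for c in counts.values() if c > 0], dtype=float)
    total = vals.sum()
    if total < 2:
        raise ValueError("Simpson index needs at least 2 stems")
    return float(1.0 - np.sum(vals * (vals - 1.0)) / (total * (total - 1.0)))


def cv_dbh(dbh_list_cm: Sequence[float]) -> float:
    """Coefficient of variation of stem DBH: sample (n-1) SD over the mean."""
    d = np.asarray(dbh_list_cm, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 stems for a CV")
    mean = d.mean()
    if mean <= 0:
        raise ValueError("mean DBH must be > 0")
    return float(d.std(ddof=1) / mean)


def hd_over_d(dom_height_m: float, mean_dbh_cm: float) -> float:
    """Slenderness ratio: dominant height (m) over mean DBH (m).

    The DBH enters in metres, so e.g. Hd = 12 m over DBH = 10 cm gives 120.
    """
    if dom_height_m <= 0 or mean_dbh_cm <= 0:
        raise ValueError("inputs must be > 0")
    return dom_height_m / (mean_dbh_cm / 100.0)


def plot_metrics(plot: PlotRecord) -> StructureMetrics:
    """All structure metrics for one plot.

    Mean DBH for Hd/D is the arithmetic stem mean when a DBH list is present,
    otherwise the quadratic mean diameter; CV requires a DBH list.
    """
    if plot.species_tally is None:
        raise ValueError(f"plot {plot.plot_id!r} has no species tally")
    mean_dbh = (
        float(np.mean(plot.dbh_list_cm)) if plot.dbh_list_cm else plot.qmd_cm
    )
    return StructureMetrics(
        shannon=shannon_index(plot.species_tally),
        simpson=simpson_index(plot.species_tally),
        cv_dbh=cv_dbh(plot.dbh_list_cm) if plot.dbh_list_cm and len(plot.dbh_list_cm) > 1 else None,
        hd_over_d=hd_over_d(plot.dom_height_m, mean_dbh),
    )


def metrics_table(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    """Per-plot metrics as a tidy DataFrame (one row per plot)."""
    rows = []
    for p in plots:
        m = plot_metrics(p)
        rows.append({
            "plot_id": p.plot_id, "shannon": m.shannon, "simpson": m.simpson,
            "cv_dbh": m.cv_dbh, "hd_over_d": m.hd_over_d,
            "altitude_m": p.altitude_m, "slope_deg": p.slope_deg,
        })
    return pd.DataFrame(rows)


def fit_covariate_model(
    sdi_values: np.ndarray,
    covariates: pd.DataFrame,
    form: str = "linear",
) -> CovariateModelFit:
    """Least-squares model of SDI on stand-structure/topography covariates.

    ``form='linear'`` regresses SDI on the covariates directly;
    ``form='log-linear'`` regresses ln SDI on them (multiplicative effects).
    The headline figure of merit is the RMSE as a percentage of the mean
    observed SDI (relative_error_pct).
    """
    sdi = np.asarray(sdi_values, dtype=float)
    if len(sdi) < 10:
        raise ValueError("need at least 10 plots")
    if covariates.isna().any().any():
        raise ValueError("missing covariate values")
    if form not in ("linear", "log-linear"):
        raise ValueError(f"unknown form {form!r}")
    X = sm.add_constant(covariates.to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear covariates")
    y = np.log(sdi) if form == "log-linear" else sdi
    fit = sm.OLS(y, X).fit()
    pred = fit.fittedvalues
    pred_sdi = np.exp(pred) if form == "log-linear" else pred
    rmse = float(np.sqrt(np.mean((sdi - pred_sdi) ** 2)))
    return CovariateModelFit(
        form=form,
        coefficients=np.asarray(fit.params),
        names=["intercept"] + list(covariates.columns),
        residual_sd=float(np.sqrt(fit.scale)),
        relative_error_pct=100.0 * rmse / float(np.mean(sdi)),
        r2=float(fit.rsquared),
    )
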