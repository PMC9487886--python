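"""Self-thinning model forms, frontier prediction, SDI projection and mortality links.

Two boundary-line forms are supported:

* Reineke's model (RM):            ln N = k + alpha * ln Dg
* variable density model (VDM):    ln N = k + alpha * ln Dg + beta * ln Hd

where N is stems/ha, Dg the quadratic mean diameter (cm) and Hd the dominant
height (m).  A fitted spec defines the boundary; from it we derive the stand
density index (density projected along the frontier to a reference size,
default 16 cm / 12 m) and the relative density N / N_frontier used both for
boundary-point selection and as the predictor of period mortality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .stand_data import PlotPair, PlotRecord, compute_mortality

RM = "RM"
VDM = "VDM"


@dataclass
class ThinningModelSpec:
    """A (possibly fitted) boundary-line specification.

    ``slope_h_beta`` is identically 0 for the RM form.  Coefficients are NaN
    until fitted when constructed via :meth:`unfitted`.
    """

    form: str
    intercept_k: float
    slope_d_alpha: float
    slope_h_beta: float = 0.0

    def __post_init__(self):
        if self.form not in (RM, VDM):
            raise ValueError(f"form must be 'RM' or 'VDM', got {self.form!r}")
        if self.form == RM and self.slope_h_beta != 0.0:
            raise ValueError("RM form requires slope_h_beta == 0")

    @classmethod
    def unfitted(cls, form: str) -> "ThinningModelSpec":
        return cls(form=form, intercept_k=math.nan, slope_d_alpha=math.nan,
                   slope_h_beta=0.0 if form == RM else math.nan)

    @property
    def is_fitted(self) -> bool:
        return not (
            math.isnan(self.intercept_k)
            or math.isnan(self.slope_d_alpha)
            or (self.form == VDM and math.isnan(self.slope_h_beta))
        )

    @property
    def coefficients(self) -> np.ndarray:
        if self.form == RM:
            return np.array([self.intercept_k, self.slope_d_alpha])
        return np.array([self.intercept_k, self.slope_d_alpha, self.slope_h_beta])

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "form": self.form,
            "intercept_k": self.intercept_k,
            "slope_d_alpha": self.slope_d_alpha,
            "slope_h_beta": self.slope_h_beta,
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThinningModelSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(form=d["form"], intercept_k=d["intercept_k"],
                   slope_d_alpha=d["slope_d_alpha"], slope_h_beta=d["slope_h_beta"])


@dataclass
class SDIReference:
    """Reference mean tree size to which density is projected (16 cm, 12 m)."""

    d0_cm: float = 16.0
    h0_m: float = 12.0

    def __post_init__(self):
        if self.d0_cm <= 0 or self.h0_m <= 0:
            raise ValueError("reference sizes must be > 0")


def design_matrix(plots: Sequence[PlotRecord], form: str) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, y) = ((1, ln Dg[, ln Hd]), ln N) for a list of plots."""
    d = np.array([p.qmd_cm for p in plots], dtype=float)
    n = np.array([p.tph for p in plots], dtype=float)
    cols = [np.ones_like(d), np.log(d)]
    if form == VDM:
        h = np.array([p.dom_height_m for p in plots], dtype=float)
        cols.append(np.log(h))
    return np.column_stack(cols), np.log(n)


def frontier_log_density(spec: ThinningModelSpec, d_cm, hd_m=None):
    """Predicted boundary ln N at mean diameter d_cm (and dominant height hd_m).

    ``hd_m`` is ignored for the RM form and required for VDM.
    """
    d_cm = np.asarray(d_cm, dtype=float)
    if np.any(d_cm <= 0):
        raise ValueError("d_cm must be > 0")
    out = spec.intercept_k + spec.slope_d_alpha * np.log(d_cm)
    if spec.form == VDM:
        if hd_m is None:
            raise ValueError("VDM frontier requires hd_m")
        hd_m = np.asarray(hd_m, dtype=float)
        if np.any(hd_m <= 0):
            raise ValueError("hd_m must be > 0")
        out = out + spec.slope_h_beta * np.log(hd_m)
    return out if out.ndim else float(out)


def sdi_projected(
    plot: PlotRecord,
    spec: ThinningModelSpec,
    ref: SDIReference = SDIReference(),
    flip: bool = False,
) -> float:
    """Stand density index: density projected along the fitted frontier to the
    reference size.

    SDI = N * (d0/Dg)^alpha [* (h0/Hg)^beta for VDM].  A plot already at the
    reference size has SDI equal to its own density.  ``flip=True`` inverts the
    size ratios (the alternative orientation sometimes printed in the
    literature), for comparison only.
    """
    if not spec.is_fitted:
        raise RuntimeError("spec is unfitted (NaN coefficients)")
    rd = ref.d0_cm / plot.qmd_cm
    rh = ref.h0_m / plot.dom_height_m
    if flip:
        rd, rh = 1.0 / rd, 1.0 / rh
    sdi = plot.tph * rd**spec.slope_d_alpha
    if spec.form == VDM:
        sdi *= rh**spec.slope_h_beta
    return float(sdi)


def relative_density(plot: PlotRecord, spec: ThinningModelSpec) -> float:
    """Actual density over frontier-predicted maximum density at the plot's size.

    R = 1 means the plot sits exactly on the boundary; R < 1 below it.
    Invariant to the SDI reference choice.
    """
    if not spec.is_fitted:
        raise RuntimeError("spec is unfitted (NaN coefficients)")
    ln_max = frontier_log_density(
        spec, plot.qmd_cm, plot.dom_height_m if spec.form == VDM else None
    )
    return float(plot.tph / math.exp(ln_max))


def mortality_density_regression(
    pairs: Sequence[PlotPair], spec: ThinningModelSpec
) -> dict:
    """OLS of period mortality on relative density R = SD / SDI_max.

    Returns slope, intercept, r2, slope_se and the two-sided p-value of the
    slope.  Crowding should drive mortality: a fitted boundary under
    self-thinning yields a positive, significant slope.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    r = np.array([relative_density(p.t0, spec) for p in pairs])
    m = np.array([compute_mortality(p) for p in pairs])
    if np.ptp(r) == 0:
        raise np.linalg.LinAlgError("relative density constant across plots")
    if np.ptp(m) == 0:
        return {"slope": 0.0, "intercept": float(m[0]), "r2": 0.0,
                "slope_se": 0.0, "slope_p": 1.0, "n": len(pairs)}
    X = sm.add_constant(r)
    fit = sm.OLS(m, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r2": float(fit.rsquared),
        "slope_se": float(fit.bse[1]),
        "slope_p": float(fit.pvalues[1]),
        "n": len(pairs),
    }
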