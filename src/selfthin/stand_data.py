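"""Plot-level stand data: records, readers, filters, splits and a synthetic generator.

The unit of observation is one inventory plot at one survey year.  Plots carry
stand density (stems/ha), quadratic mean diameter Dg (cm), dominant height Hd
(m, arithmetic mean of the seven dominant trees), site descriptors and optional
per-species stem tallies / per-stem DBH lists.  Repeated surveys of the same
plot form a :class:`PlotPair`, from which period mortality is computed as the
number of dead stems divided by the initial stem count.

The synthetic generator draws stands whose log-density sits a one-sided
"inefficiency" distance below a stochastic frontier

    ln N = k + alpha * ln Dg + beta * ln Hd + v - u,   v ~ N(0, sigma_v^2), u >= 0,

with Hd allometrically coupled to Dg and period mortality increasing linearly
with relative density N / N_frontier.  This is the data-generating structure
the frontier estimators in :mod:`selfthin.sfa_frontier` assume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Plot area of the inventory design emulated by the generator: 25.82 m squares,
#: i.e. 1/15 ha, so stems/ha = 15 * stem count.
PLOT_AREA_HA = 25.82 * 25.82 / 1e4

_MANDATORY_COLUMNS = (
    "plot_id",
    "year",
    "tph",
    "qmd_cm",
    "dom_height_m",
    "oak_fraction",
    "altitude_m",
    "slope_deg",
)


class PlotValidationError(ValueError):
    """A row (or record) violates a hard constraint; carries offending ids."""

    def __init__(self, message: str, row_ids: Sequence | None = None):
        super().__init__(message)
        self.row_ids = list(row_ids) if row_ids is not None else []


class PlotFormatError(ValueError):
    """The input table is structurally unusable (e.g. missing a column)."""


@dataclass
class PlotRecord:
    """One plot x survey-year observation.

    DBH values below the 5 cm recording limit are never present in
    ``dbh_list_cm``; ``species_tally`` maps species name to stem count and,
    when present, must agree with the stem count implied by ``tph`` to within
    one stem of rounding.
    """

    plot_id: str
    year: int
    tph: float
    qmd_cm: float
    dom_height_m: float
    oak_fraction: float = 0.0
    altitude_m: float = 0.0
    slope_deg: float = 0.0
    basal_area_m2ha: float | None = None
    canopy_density: float | None = None
    species_tally: dict[str, int] | None = None
    dbh_list_cm: list[float] | None = None

    def __post_init__(self):
        if self.tph <= 0:
            raise PlotValidationError(
                f"plot {self.plot_id!r}: tph must be > 0, got {self.tph}",
                [self.plot_id],
            )
        if self.qmd_cm <= 0 or self.dom_height_m <= 0:
            raise PlotValidationError(
                f"plot {self.plot_id!r}: non-positive size "
                f"(qmd_cm={self.qmd_cm}, dom_height_m={self.dom_height_m})",
                [self.plot_id],
            )
        if not 0.0 <= self.oak_fraction <= 1.0:
            raise PlotValidationError(
                f"plot {self.plot_id!r}: oak_fraction outside [0, 1]", [self.plot_id]
            )
        if self.canopy_density is not None and not 0.0 <= self.canopy_density <= 1.0:
            raise PlotValidationError(
                f"plot {self.plot_id!r}: canopy_density outside [0, 1]", [self.plot_id]
            )
        if self.dbh_list_cm is not None and len(self.dbh_list_cm) > 0:
            if min(self.dbh_list_cm) < 5.0:
                raise PlotValidationError(
                    f"plot {self.plot_id!r}: DBH below the 5 cm recording limit",
                    [self.plot_id],
                )
        if self.species_tally is not None:
            total = sum(self.species_tally.values())
            implied = self.tph * PLOT_AREA_HA
            if abs(total - implied) > 1.0 + 1e-9:
                raise PlotValidationError(
                    f"plot {self.plot_id!r}: species tally ({total} stems) "
                    f"inconsistent with tph ({implied:.2f} stems/plot)",
                    [self.plot_id],
                )

    @property
    def stem_count(self) -> int:
        """Stems on the plot: the tally total if present, else round(tph * area)."""
        if self.species_tally is not None:
            return int(sum(self.species_tally.values()))
        return int(round(self.tph * PLOT_AREA_HA))


@dataclass
class PlotPair:
    """The same plot at two surveys plus the count of stems that died between."""

    t0: PlotRecord
    t1: PlotRecord
    n_dead: int

    def __post_init__(self):
        if self.t0.year >= self.t1.year:
            raise PlotValidationError(
                f"plot {self.t0.plot_id!r}: t0.year must precede t1.year",
                [self.t0.plot_id],
            )
        if self.n_dead < 0 or self.n_dead > self.t0.stem_count:
            raise PlotValidationError(
                f"plot {self.t0.plot_id!r}: n_dead={self.n_dead} outside "
                f"[0, {self.t0.stem_count}]",
                [self.t0.plot_id],
            )


def compute_mortality(pair: PlotPair) -> float:
    """Period mortality: dead stems divided by the initial stem count, in [0, 1]."""
    n0 = pair.t0.stem_count
    if n0 <= 0:
        raise PlotValidationError(
            f"plot {pair.t0.plot_id!r}: zero stems at first survey", [pair.t0.plot_id]
        )
    return pair.n_dead / n0


def read_plot_table(path, column_map: Mapping[str, str] | None = None) -> list[PlotRecord]:
    """Read a plot table CSV (one row per plot x year) into validated records.

    Parameters
    ----------
    path
        CSV file with a header row.  Mandatory columns: plot_id, year, tph,
        qmd_cm, dom_height_m, oak_fraction, altitude_m, slope_deg.  Optional:
        basal_area_m2ha, canopy_density, plus any number of ``sp_<name>``
        per-species tally columns and a semicolon-separated ``dbh_list_cm``.
    column_map
        Optional mapping from the canonical names above to the names actually
        used in the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise PlotFormatError(f"plot table missing mandatory column(s): {missing}")

    bad = df.index[(df["tph"] <= 0) | (df["qmd_cm"] <= 0) | (df["dom_height_m"] <= 0)]
    if len(bad):
        ids = df.loc[bad, "plot_id"].tolist()
        raise PlotValidationError(
            f"non-positive density/size in rows for plots {ids}", ids
        )

    sp_cols = [c for c in df.columns if c.startswith("sp_")]
    records = []
    for _, row in df.iterrows():
        tally = None
        if sp_cols:
            tally = {
                c[3:]: int(row[c]) for c in sp_cols if pd.notna(row[c]) and row[c] > 0
            }
            if not tally:
                tally = None
        dbh = None
        if "dbh_list_cm" in df.columns and pd.notna(row["dbh_list_cm"]):
            dbh = [float(x) for x in str(row["dbh_list_cm"]).split(";") if x]
        records.append(
            PlotRecord(
                plot_id=str(row["plot_id"]),
                year=int(row["year"]),
                tph=float(row["tph"]),
                qmd_cm=float(row["qmd_cm"]),
                dom_height_m=float(row["dom_height_m"]),
                oak_fraction=float(row["oak_fraction"]),
                altitude_m=float(row["altitude_m"]),
                slope_deg=float(row["slope_deg"]),
                basal_area_m2ha=(
                    float(row["basal_area_m2ha"])
                    if "basal_area_m2ha" in df.columns and pd.notna(row["basal_area_m2ha"])
                    else None
                ),
                canopy_density=(
                    float(row["canopy_density"])
                    if "canopy_density" in df.columns and pd.notna(row["canopy_density"])
                    else None
                ),
                species_tally=tally,
                dbh_list_cm=dbh,
            )
        )
    logger.info("read %d plot records from %s", len(records), path)
    return records


def apply_inclusion_filters(
    plots: Sequence[PlotRecord],
    min_canopy: float = 0.60,
    min_tph: float = 500.0,
    min_oak: float = 0.15,
) -> list[PlotRecord]:
    """Keep plots meeting the inclusion criteria of the study design.

    Canopy density and stems/ha are compared strictly (``> min_canopy``,
    ``> min_tph``); the oak share uses ``>= min_oak``.  Plots without a
    recorded canopy density fail the canopy criterion.
    """
    kept = [
        p
        for p in plots
        if p.canopy_density is not None
        and p.canopy_density > min_canopy
        and p.tph > min_tph
        and p.oak_fraction >= min_oak
    ]
    logger.info(
        "inclusion filters kept %d / %d plots (canopy>%g, tph>%g, oak>=%g)",
        len(kept), len(plots), min_canopy, min_tph, min_oak,
    )
    return kept


def split_modeling_validation(
    plots: Sequence, frac: float = 0.7, seed: int | None = None
) -> tuple[list, list]:
    """Random disjoint split into a modeling set of round(frac*n) plots and the rest.

    Deterministic for a given seed; the two sets partition the input.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    n = len(plots)
    if n < 2:
        raise ValueError("need at least 2 plots to split")
    # nearest integer, half-values rounding down: 0.7 * 265 = 185.5 -> 185
    n_model = int(math.ceil(frac * n - 0.5))
    n_model = min(max(n_model, 1), n - 1)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    model_idx = set(idx[:n_model].tolist())
    modeling = [plots[i] for i in range(n) if i in model_idx]
    validation = [plots[i] for i in range(n) if i not in model_idx]
    return modeling, validation


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic stand generator.

    Defaults reproduce the study conditions of the oak mixed-forest frontier:
    the frontier coefficients and error variances are the truncated-normal
    variable-density estimates (k=8.424, alpha=-0.996, beta=0.621,
    sigma_v2=0.301, sigma_u2=0.378), Dg is lognormal so that the simulated
    quadratic mean diameters bracket the observed 6.9-23.1 cm range, the
    allometry puts dominant height in the observed 6-16 m range, and the
    mortality link yields a mean period mortality near 35%.
    """

    k: float = 8.424
    alpha: float = -0.996
    beta: float = 0.621
    sigma_v2: float = 0.301
    sigma_u2: float = 0.378
    mu: float = 0.0
    dist: str = "half_normal"  # half_normal | exponential | truncated_normal
    d_logmean: float = math.log(11.0)
    d_logsd: float = 0.25
    allom_a: float = 2.5
    allom_b: float = 0.6
    allom_sd: float = 0.28
    mort_intercept: float = 0.0
    mort_slope: float = 0.47
    mort_sd: float = 0.08
    growth_rate: float = 0.10
    n_plots: int = 185
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_v2 < 0 or self.sigma_u2 < 0:
            raise ValueError("error variances must be >= 0")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.dist not in ("half_normal", "exponential", "truncated_normal"):
            raise ValueError(f"unknown one-sided distribution {self.dist!r}")


def _draw_one_sided(rng, dist: str, sigma_u2: float, mu: float, size: int):
    """Draw u >= 0 with *variance parameter* sigma_u2 under the named law.

    For half-normal and truncated-normal, sigma_u2 is the pre-truncation
    variance; for exponential it is the squared scale (mean^2).
    """
    if sigma_u2 == 0:
        return np.zeros(size)
    su = math.sqrt(sigma_u2)
    if dist == "half_normal":
        return np.abs(rng.normal(0.0, su, size))
    if dist == "exponential":
        return rng.exponential(su, size)
    # truncated normal, left-truncated at 0 with pre-truncation mean mu
    a = (0.0 - mu) / su
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=su, size=size, random_state=rng)


def simulate_stands(config: SyntheticConfig) -> tuple[list[PlotPair], dict]:
    """Simulate plot pairs from the frontier + mortality data-generating process.

    Returns the pairs and a record of the true generating quantities (frontier
    parameters, per-plot u, v, relative density and latent mortality) for use
    in recovery experiments.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.n_plots

    dg = rng.lognormal(c.d_logmean, c.d_logsd, n)
    hd = c.allom_a * dg**c.allom_b * np.exp(rng.normal(0.0, c.allom_sd, n))
    v = rng.normal(0.0, math.sqrt(c.sigma_v2), n) if c.sigma_v2 > 0 else np.zeros(n)
    u = _draw_one_sided(rng, c.dist, c.sigma_u2, c.mu, n)
    ln_n = c.k + c.alpha * np.log(dg) + c.beta * np.log(hd) + v - u
    tph = np.exp(ln_n)

    # relative density against the true (noise-free) frontier
    rel_density = np.exp(v - u)
    latent_mort = c.mort_intercept + c.mort_slope * rel_density
    if c.mort_sd > 0:
        latent_mort = latent_mort + rng.normal(0.0, c.mort_sd, n)
    latent_mort = np.clip(latent_mort, 0.0, 1.0)

    pairs = []
    for i in range(n):
        t0 = PlotRecord(
            plot_id=f"S{i:04d}",
            year=2004,
            tph=float(tph[i]),
            qmd_cm=float(dg[i]),
            dom_height_m=float(hd[i]),
            oak_fraction=float(rng.uniform(0.15, 0.82)),
            altitude_m=float(rng.uniform(43.0, 1470.0)),
            slope_deg=float(rng.uniform(0.0, 50.0)),
            canopy_density=float(rng.uniform(0.61, 0.95)),
        )
        n0 = t0.stem_count
        n_dead = int(round(latent_mort[i] * n0))
        n_dead = min(max(n_dead, 0), max(n0 - 1, 0))
        surv_frac = 1.0 - n_dead / n0 if n0 > 0 else 1.0
        t1 = replace(
            t0,
            year=2014,
            tph=max(t0.tph * surv_frac, 1e-6),
            qmd_cm=t0.qmd_cm * (1.0 + c.growth_rate),
            dom_height_m=t0.dom_height_m * (1.0 + c.growth_rate),
        )
        pairs.append(PlotPair(t0=t0, t1=t1, n_dead=n_dead))

    truth = {
        "k": c.k,
        "alpha": c.alpha,
        "beta": c.beta,
        "sigma_v2": c.sigma_v2,
        "sigma_u2": c.sigma_u2,
        "mu": c.mu,
        "dist": c.dist,
        "u": u,
        "v": v,
        "relative_density": rel_density,
        "latent_mortality": latent_mort,
    }
    return pairs, truth


def attach_species_tallies(
    pairs: Sequence[PlotPair],
    seed: int | None = None,
    n_species_range: tuple[int, int] = (3, 8),
    evenness: float = 1.0,
) -> list[PlotPair]:
    """Attach synthetic per-species tallies and DBH lists to simulated pairs.

    Species proportions are Dirichlet(evenness); stem DBHs are drawn lognormal
    around each plot's Dg (left-truncated at the 5 cm recording limit) so that
    diversity and structure metrics can be computed on generated stands.
    """
    rng = np.random.default_rng(seed)
    out = []
    for pair in pairs:
        t0 = pair.t0
        n0 = t0.stem_count
        s = int(rng.integers(n_species_range[0], n_species_range[1] + 1))
        props = rng.dirichlet(np.full(s, evenness))
        counts = rng.multinomial(n0, props)
        tally = {f"sp{j}": int(c) for j, c in enumerate(counts) if c > 0}
        dbh = rng.lognormal(math.log(max(t0.qmd_cm, 5.5)) - 0.02, 0.2, n0)
        dbh = np.maximum(dbh, 5.0)
        t0 = replace(t0, species_tally=tally, dbh_list_cm=[float(x) for x in dbh])
        out.append(PlotPair(t0=t0, t1=pair.t1, n_dead=pair.n_dead))
    return out
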