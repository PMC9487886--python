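import numpy as np
import pytest

from selfthin import (
    PlotPair,
    PlotRecord,
    SyntheticConfig,
    simulate_stands,
)


def make_plot(plot_id="p1", year=2004, tph=1500.0, qmd_cm=11.0, dom_height_m=12.0,
              **kw) -> PlotRecord:
    kw.setdefault("oak_fraction", 0.4)
    kw.setdefault("altitude_m", 500.0)
    kw.setdefault("slope_deg", 20.0)
    return PlotRecord(plot_id=plot_id, year=year, tph=tph, qmd_cm=qmd_cm,
                      dom_height_m=dom_height_m, **kw)


def make_pair(plot_id="p1", tph0=1500.0, n_dead=30, **kw) -> PlotPair:
    t0 = make_plot(plot_id=plot_id, year=2004, tph=tph0, **kw)
    t1 = make_plot(plot_id=plot_id, year=2014, tph=max(tph0 - 15 * n_dead, 1.0), **kw)
    return PlotPair(t0=t0, t1=t1, n_dead=n_dead)


@pytest.fixture(scope="session")
def default_pairs():
    """One simulated stand sample at the default study conditions (n=185)."""
    pairs, truth = simulate_stands(SyntheticConfig(seed=42))
    return pairs, truth


@pytest.fixture(scope="session")
def default_plots(default_pairs):
    pairs, _ = default_pairs
    return [p.t0 for p in pairs]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
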