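"""Stand density index, relative density and the mortality-crowding link.

Projects every plot's density along a fitted frontier to the 16 cm / 12 m
reference size (SDI), regresses decade mortality on relative density, and
runs the holdout t-test that checks the frontier transfers to unseen plots.
"""

import numpy as np

from selfthin import (
    SyntheticConfig, VDM, fit_sfa, mortality_density_regression,
    relative_density, sdi_projected, simulate_stands,
    split_modeling_validation, validate_holdout,
)
from selfthin.density_models import design_matrix

pairs, _ = simulate_stands(SyntheticConfig(n_plots=265, seed=13))
plots = [p.t0 for p in pairs]
modeling, validation = split_modeling_validation(plots, 0.7, seed=13)
print(f"split: {len(modeling)} modeling / {len(validation)} validation plots")

X, y = design_matrix(modeling, VDM)
fit = fit_sfa(X, y, dist="NH", seed=0)

sdi = np.array([sdi_projected(p, fit.spec) for p in modeling])
rel = np.array([relative_density(p, fit.spec) for p in modeling])
print(f"SDI at 16 cm / 12 m: mean {sdi.mean():.0f} stems/ha "
      f"(range {sdi.min():.0f}-{sdi.max():.0f})")
print(f"relative density SD/SDI_max: mean {rel.mean():.2f}, "
      f"{np.mean(rel >= 1.0) * 100:.0f}% of plots at or above the frontier")

ids = {p.plot_id for p in modeling}
reg = mortality_density_regression([p for p in pairs if p.t0.plot_id in ids],
                                   fit.spec)
print(f"mortality ~ relative density: slope {reg['slope']:.2f} "
      f"(p={reg['slope_p']:.1e}), R2 {reg['r2']:.2f}")

t = validate_holdout(fit, modeling, validation)
print(f"holdout SDI t-test: t={t['t_stat']:.2f}, p={t['p_value']:.3f} "
      f"(means {t['mean_modeling']:.0f} vs {t['mean_validation']:.0f})")
print("\nA positive mortality slope confirms crowding drives tree death; a "
      "non-significant t-test says the frontier projects consistently onto "
      "plots it never saw.")
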