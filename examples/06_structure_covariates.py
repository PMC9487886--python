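"""Stand-structure diversity metrics and the SDI covariate model.

Computes Shannon/Simpson diversity, DBH variation and the slenderness ratio
Hd/D per plot, then models projected maximum density (SDI) as a linear
function of altitude, Simpson index and Hd/D.
"""

import numpy as np

from selfthin import (
    SyntheticConfig, VDM, attach_species_tallies, fit_covariate_model,
    fit_sfa, metrics_table, sdi_projected, simulate_stands,
)
from selfthin.density_models import design_matrix

pairs, _ = simulate_stands(SyntheticConfig(n_plots=185, seed=31))
pairs = attach_species_tallies(pairs, seed=32)
plots = [p.t0 for p in pairs]

tbl = metrics_table(plots)
print("structure metrics over", len(tbl), "plots:")
for col in ("shannon", "simpson", "cv_dbh", "hd_over_d"):
    print(f"  {col:10s} mean {tbl[col].mean():7.2f}  "
          f"range {tbl[col].min():6.2f}-{tbl[col].max():6.2f}")

X, y = design_matrix(plots, VDM)
fit = fit_sfa(X, y, dist="NH", seed=0)
sdi = np.array([sdi_projected(p, fit.spec) for p in plots])

cov = fit_covariate_model(sdi, tbl[["altitude_m", "simpson", "hd_over_d"]],
                          form="linear")
print("\nSDI ~ altitude + Simpson + Hd/D (linear):")
for name, coef in zip(cov.names, cov.coefficients):
    print(f"  {name:10s} {coef:10.3f}")
print(f"  relative error {cov.relative_error_pct:.1f}% of mean SDI, "
      f"R2 {cov.r2:.3f}")
print("\nDiversity and topography are generated independently of density, so "
      "the model finds little signal here (R2 near 0); on field data the same "
      "call quantifies how site and structure shift the carrying capacity.")
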