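# Methods

## Model

Stand density is modelled as bounded above by a log-linear frontier in mean
tree size. Writing N for stems/ha, Dg for quadratic mean diameter (cm) and
Hd for dominant height (m, arithmetic mean of the 7 dominant trees):

* Reineke's model (RM): ln N = φ1 + φ2 ln Dg
* variable density model (VDM): ln N = k + α ln Dg + β ln Hd

The VDM follows from combining the allometric mean-mass/density
(self-thinning) power law with mass as a power function of diameter and
height; the derivation constants are absorbed into (k, α, β) and never
stored. α is interpreted as the self-thinning rate and β as the change in
maximum carrying capacity with stand stature; the expected sign pattern is
α < 0, β > 0.

## Estimators

**Quantile regression.** The τ-th quantile line minimises the check loss
Σ ρ_τ(y − Xγ). We solve it exactly as a linear program (residuals split into
positive/negative parts; HiGHS interior point/simplex), so there is no
smoothing parameter and the optimum interpolates ≥ p data points. Default
path τ ∈ {0.900, 0.925, 0.950, 0.975, 0.990}; per-τ failures are recorded
without aborting the path. Confidence intervals are percentile bootstrap
over (x, y)-pair resampling (the construction behind published interval
plots for boundary-line quantile fits is generally unstated; pair
resampling is our choice, and it is reproducible under a seed). A
brute-force oracle that scores every line through a pair of data points
backs the solver in tests.

**Stochastic frontier ML.** The frontier orientation is production-style,
ε = v − u with u ≥ 0, because density is bounded *above*. Marginal
log-densities of ε are the classical closed forms: Aigner–Lovell–Schmidt for
normal–half-normal, Meeusen–van den Broeck for normal–exponential, and
Stevenson's truncated-normal generalisation with pre-truncation mean μ
(NH ≡ NT at μ = 0). σu² denotes the pre-truncation variance for NH/NT and
the squared scale for NE. Estimation maximises the sample log-likelihood
over (β, ln σv², ln σu²[, μ]) with L-BFGS-B; the log-variance
parameterisation makes positivity implicit. Starting values are
corrected OLS (residual variance split evenly, intercept shifted by the
implied E[u]) plus four jittered replicas with fixed sub-seeds; the best
converged optimum is returned. Bounds ln σ² ∈ [−8, 5] and μ ∈ [−5, 5] keep
the optimiser off degenerate rays (see limitations). Convergence uses
L-BFGS-B's relative-f and gradient criteria (ftol 1e−12, gtol 1e−7);
σu² < 1e−3 at the optimum raises a boundary flag, since there the frontier
is indistinguishable from mean regression. AIC = 2k − 2 lnL with k counting
frontier coefficients + 2 variance parameters (+ μ for NT), the convention
of common econometric software. RM-vs-VDM comparison uses ΔAIC and the LRT
(χ²₁, since RM is VDM with β = 0). Inefficiency is predicted by the
Jondrow-type conditional mean E[u | ε] for the fitted law.

**Standard errors.** Primary SEs are BHHH (outer product of per-observation
score vectors, central differences in the working parameterisation, delta
method back to the variance scale); the finite-difference Hessian of the
negative log-likelihood is the fallback when the OPG matrix is not
invertible. We prefer OPG because when a variance component drifts toward
its boundary — which the NT law does on a non-negligible fraction of
samples at n ≈ 185 — the local quadratic of the likelihood understates the
estimator's actual dispersion, while the score outer product remains
informative; in recovery simulations OPG restores near-nominal 2-SE
coverage for the intercept where Hessian SEs under-cover.

## Density index and derived quantities

SDI projects a plot's density along the fitted frontier to a reference mean
size, default (D0, H0) = (16 cm, 12 m):

SDI = N · (D0/Dg)^α [· (H0/Hg)^β].

This orientation is the one that preserves a plot's ratio to the boundary
(a plot at the reference size keeps its own density; the projection is
frontier-consistent). An option flips the ratio convention for comparison
with sources that print the inverse. Relative density
R = N / exp(frontier ln N at the plot's own size) is reference-free; R = 1
is the boundary. Mortality (dead stems between surveys / initial stems) is
regressed on R by OLS; under self-thinning the slope is positive. Holdout
validation applies a Welch two-sample t-test (variant unspecified in the
boundary-line literature; unequal variances is the safe default) to
projected SDI between the modeling and validation splits.

The 70/30 split uses the nearest integer with half-values rounding down
(so 265 plots give 185/80) and is deterministic given a seed. Inclusion
filters keep plots with canopy density > 0.60 (strict), stems/ha > 500
(strict) and oak share ≥ 0.15 (inclusive); the conventions only differ at
exact boundary values and are logged.

## Traditional selection methods

Four rules pick "boundary" plots for an OLS fit: (i) interval — the densest
plot(s) per equal-width ln Dg bin (bin count is never standardised in the
literature; default 10, configurable); (ii) mortality — plots whose decade
mortality reaches a threshold, default 20%, exposed because the plantation
convention transfers poorly to mixed stands where much mortality is
light-driven; (iii) relative density ≥ a standard (default 1.0) against a
provisional line; (iv) upper convex hull in (ln Dg, ln N) — an objective,
reproducible surrogate for the subjective visual tracing of the scatter's
upper edge, and labelled as a surrogate in outputs. Degenerate inputs
(duplicate diameters, collinear scatters) fall back to the densest plot per
distinct diameter / return all points.

## Synthetic stand generator

The generator emulates subtropical oak mixed-forest inventory plots
(1/15-ha squares, two surveys a decade apart):

* Dg ~ lognormal(ln 11, 0.25) cm — brackets the observed 6.9–23.1 cm range;
* Hd = 2.5 · Dg^0.6 · exp(N(0, 0.28²)) m — mean heights near 11–12 m. The
  residual height spread 0.28 is chosen to match the precision with which
  the height coefficient is estimable in field data of this size (an SE
  near 0.17 at n = 185), which is the feature that matters for method
  evaluation; it implies somewhat more height variation at fixed diameter
  than the marginal height spread of the motivating inventory;
* ln N = k + α ln Dg + β ln Hd + v − u with defaults
  k = 8.424, α = −0.996, β = 0.621, σv² = 0.301, σu² = 0.378 (half-normal
  u; exponential and truncated-normal available) — the truncated-normal
  VDM estimates for oak mixed forests;
* decade mortality = clip(0 + 0.47·R + N(0, 0.08²), 0, 1) with R = e^{v−u}
  the true relative density. Slope 0.47 with intercept 0 gives mean
  mortality ≈ 35% at the default error scales (E[R] ≈ 0.755, computed from
  the half-normal moments), matching the motivating inventory's decade
  mortality. The second survey thins stems by the drawn mortality and grows
  sizes by a configurable 10%/decade;
* site covariates (altitude 43–1470 m, slope 0–50°, canopy 0.61–0.95, oak
  share 0.15–0.82) are uniform and independent of density; species tallies
  (3–8 species, Dirichlet-multinomial) and stem DBH lists (lognormal about
  Dg, left-truncated at the 5 cm recording limit) can be attached for
  structure metrics.

What the generator does *not* emulate: spatial or environmental structure
(site quality does not shift the frontier, diversity is independent of
density), the response-side truncation of plot-selection rules (simulated
stands are the post-selection population, so the inclusion filters should
not be re-applied to them), measurement error in Dg/Hd, and ingrowth.
Passing tests therefore demonstrate estimator correctness under the assumed
data-generating process, not robustness to field-data pathologies such as
frontier heterogeneity across sites.

## Numerical choices and degenerate inputs

All Φ terms use stable log-CDFs. σu² = 0 is handled analytically (pure
normal, E[u|ε] = 0). The LRT statistic is floored at 0 against optimiser
tolerance. Quantile LP non-convergence and rank-deficient designs raise
typed errors carrying diagnostics; a zero-stem first survey, empty species
tallies and non-positive sizes are rejected at construction. Hull turn
tests use a scale-relative tolerance so exactly-collinear scatters are kept
whole. Problem sizes in the test suite are chosen to make each stochastic
check sharp at desk scale: 50 oracle instances for the LP, 10⁶ draws for
density and inefficiency cross-checks, 100 replicates of n = 185 for
recovery, 200/100 replicates for LRT size/power, 100 replicates for
bootstrap coverage.

## Known limitations

* The NT likelihood has a weakly identified ridge at moderate n: μ → large
  with σv² → 0 yields nearly the same likelihood as interior parameter
  values (differences of ~1 log-lik unit), because a truncated normal with
  large positive μ degenerates to a shifted normal. Slopes are essentially
  unaffected; intercept, μ and the variance split are uncertain, which the
  OPG SEs reflect. The bounds on ln σ² act as the compactification that
  makes the reported optimum well-defined; interpret NT variance components
  with care and prefer NH/NE when their AIC is close.
* Quantile fits at τ ≥ 0.975 depend on a handful of points at n ≈ 185 and
  can be unstable (non-convergence at τ = 0.990 on near-degenerate designs
  is expected behaviour and reported per-τ rather than raised).
* The SDI covariate model is a descriptive least-squares fit (linear or
  log-linear; the functional form in this literature is never stated); it
  makes no causal claim about site effects on carrying capacity.
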