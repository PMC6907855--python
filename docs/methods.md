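# Methods

This note documents the models implemented in `vipermass`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The mass-action incidence model

The core model treats snakebite as the outcome of random encounters
between an exposed rural population and a venomous-snake population.
With perfect mixing, encounters in district *i* are proportional to
`S_i * V_i` (exposed people × snakes); multiplying by the probability
`theta` that an encounter ends in a bite gives the incidence. Because
absolute snake abundance `V_i` is impractical to census, the contact
rate and abundance are folded into a single measurable quantity — the
encounter frequency `F_i`, snakes detected per person-hour of
standardized active search — giving the regression form

```
I_i = alpha + theta * F_i * S_i + eps_i,   eps_i ~ N(0, sigma^2)
```

`alpha` (cases/year) absorbs whatever mean incidence is not explained by
the mass-action product and forces the residuals to average zero; as a
consequence the fitted national total equals the reported national total
for every model that carries an intercept. `theta` is dimensionally a
bite probability per encounter-unit; its numeric scale depends on the
units chosen for `F*S`, and the package's synthetic truth uses
`theta = 1e-3` so that districts with realistic rural populations
(log-normal, median ≈ 3 000) and encounter frequencies (0–0.3 per
person-hour) span roughly 0–15 cases/year. A `theta` printed under a
different unit convention (e.g. of order 1e-6) describes the same model
with `F*S` measured on a correspondingly larger scale; every recovery
and coverage check here is invariant to that scale.

### Candidate structures and comparison

Five OLS structures are compared: the mass-action model with and without
intercept, population-only, encounter-frequency-only, and the additive
two-predictor model. Comparison uses centered R² (also for the
no-intercept model, flagged in output, so all rows share one scale) and
AIC under the Gaussian likelihood counting the error variance as a
parameter:

```
AIC = n ln(2 pi RSS / n) + n + 2 (k + 1)
```

This is the convention of common statistical software up to the constant
`+2` relative to implementations that do not count `sigma^2`; AIC
*differences* between models, which drive selection, are unaffected.

### Intervals, diagnostics, outliers

Confidence and prediction bands are standard t-based OLS intervals at
level 0.99. Districts whose observed incidence escapes their own 99%
prediction band are flagged under- or over-estimated; bands vary with
the predictor, so the per-district half-width and the half-width at the
mean predictor are both reported. The residual-vs-fitted Pearson test is
included for fidelity to the calibration protocol; for intercept OLS the
correlation is identically zero by orthogonality, so it is informative
only for the no-intercept structure (where curvature left in the
residuals is detectable). No multiple-testing correction is applied to
outlier flags.

The national estimate's range is a t interval on the summed fitted
values using the coefficient covariance, `total ± t_{0.995,dof} *
sqrt(1'X Cov(beta) X'1)`. Other conventions (e.g. summing per-district
intervals) would give wider ranges; the covariance-based one matches the
uncertainty of the total as a linear functional of the coefficients.

### Multi-species extension

Where several species contribute bites, the model generalizes to
`I_i = alpha + sum_j theta_j * F_j,i * S_i`, fitted as a multiple
regression on the products `F_j,i * S_i`. With one species this reduces
exactly to the single-species fit; collinear species columns are
rejected by name.

## The maximum-entropy distribution model

Presence-background species distribution modelling is implemented as the
Gibbs distribution `p(cell) ∝ exp(lambda · f(cell))` over background
cells — the maximum-entropy distribution subject to matching the
presence means of the features `f`. Features are linear and quadratic
transforms of each covariate, standardized by background mean/sd;
feature classes richer than quadratic (hinge, product, threshold) are
deliberately out of scope, keeping the likelihood strictly convex and
the fit reproducible. Fitting maximizes the L1-penalized presence
log-likelihood via an equivalent smooth bound-constrained problem
(each weight split into positive and negative parts, L-BFGS-B);
stationarity is verified against the L1 subgradient condition at
tolerance 1e-6, and a failed check raises an error carrying the
violating gradient entries. At zero penalty the fitted model reproduces
the classic moment condition (model expected features = presence means);
with penalty `reg` each model expectation lies within `reg` of the
presence mean.

Defaults: global L1 multiplier 0.1; presences collapsed to one per cell
(blunts trivial sampling-bias duplication); training background = all
valid cells up to 1e5 cells, else a uniform sample of 1e4. Evaluation
AUC uses an independently seeded draw of 1 000 background cells
*excluding* presence cells (exclusion makes the null AUC exactly 0.5)
and is computed by the rank-sum estimator with the usual half-credit for
ties. The presence/absence map uses the zero-omission threshold — the
minimum suitability across training presences, which among presence-
defined operating points keeps every training record predicted present
while maximizing predicted area — and then removes cells above the
species' altitudinal ceiling (default 1200 m).

Grids follow one convention throughout: cell centers, row-major storage,
origin at the upper-left corner, 0-based indices. Inputs must be
pre-aligned; misalignment is an error, never a silent resample.

## Encounter rates and their spatialization

Survey records hold person-hours and counts per active-search session.
Stratum rates are pooled — total counts over total effort — so the
estimate is the maximum-likelihood rate of a Poisson count process and
is invariant to how effort is split across records; a mean of per-record
ratios would weight a 1-hour walk equally with a 30-hour campaign.
Season and land cover are recorded but pooled into (versant × altitude
band) strata for extrapolation, because those are the two axes along
which the focal species' abundance is known to vary and along which the
rates are painted over the map. Altitude bands are closed on the left:
[0, 400), [400, 800), [800, ∞) metres. A stratum that occurs under the
predicted range but was never surveyed inherits the versant-level pooled
rate, with a prominent log line; if even the versant is unsurveyed, the
extrapolation fails listing the offending strata.

District encounter frequency `F_i` is the arithmetic mean of the
encounter surface over *all* valid cells of the district, with
predicted-absence cells contributing zero. `F_i` therefore mixes
within-range rates with the fraction of the district the species
occupies — the quantity that drives expected encounters for a uniformly
distributed population.

## The synthetic-data generator

The generator emulates the study system's structure with known ground
truth:

- **Covariates**: Gaussian white noise smoothed with a fixed-width
  kernel (sigma 3 cells), then standardized — spatially autocorrelated
  but stationary, unlike real bioclimatic layers with trends and
  cross-correlations.
- **Elevation and versants**: a smooth ridge (plus smoothed noise)
  rescaled to [0, 1600] m splits each row at its crest into two
  versants, mimicking a Pacific/Caribbean divide.
- **Districts**: nearest-centroid (Voronoi) partition around random
  cells — contiguous by construction, without polygon geometry.
- **Occurrences**: cells drawn with probability ∝ `exp(w · covariates)`
  *within the true range*, jittered within cells. The true range is the
  upper tail of the same log-linear suitability (default: top 55%,
  matching a species occupying roughly half the territory) clipped to
  the altitude ceiling; records are not generated outside it, since the
  species is absent there.
- **Surveys**: focal counts are Poisson(rate × effort) per stratum, with
  independent Poisson layers for other venomous and non-venomous snakes
  scaled so the expected composition matches the field ratios (focal ≈
  0.7 of venomous, ≈ 0.45 of all snakes). Default stratum rates decline
  with altitude and differ by versant, pooling to ≈ 0.15 per
  person-hour.
- **Census**: log-normal positive integers (median ≈ 3 000, heavy right
  tail).
- **Incidence**: `alpha + theta * F_i * S_i` plus Gaussian noise
  (default) or a Poisson draw. Gaussian draws are floored at zero in
  pipeline data — incidence is a count — but regression-study tables
  (`make_district_table`) leave the noise unfloored, because flooring
  censors low-incidence districts and would bias coefficient-recovery
  simulations by construction; negative synthetic values trigger a
  warning downstream rather than an error.
- **Noise calibration**: `noise_sd_for_r2` sets the noise sd from the
  realized signal variance so the expected fit R² hits a target
  (default 0.66, the headline goodness of fit the model family attains
  on real district data).

One integer seed determines every generated artifact; sub-seeds for the
pipeline stages are derived from it deterministically.

What passing tests on these data do **not** show: robustness to
covariate collinearity and non-stationarity, to spatially clustered or
biased occurrence sampling, to imperfect detection in surveys, to
within-district population heterogeneity (the model treats `S_i` as a
scalar), or to reporting artifacts in incidence data (cases attributed
to the treating district rather than the bite location). Those are real
features of field data that the study-design discussion must carry.

## Problem sizes and numerical choices

Default test and demonstration runs use grids of a few thousand cells,
150 occurrence records, and 12–200 districts; the acceptance script's
end-to-end run uses 193 districts — the study's own sample size — on a
90×120 grid, and 100-replicate simulations for coverage and model
selection. Coverage of the 99% CI for `theta` is checked over 100
replicates; estimator bias over 1 000 replicates, where the 2-SE
Monte-Carlo bound is tight enough (≈ 0.3% of `theta`) to exclude a
percent-level bias rather than merely failing to detect one.

Degenerate inputs are handled explicitly: zero-variance covariates are
dropped with a warning; a constant suitability map scores AUC 0.5 with a
warning; RSS = 0 yields AIC −∞ behind a warning rather than an
exception; zero-variance residuals make the residual-fitted correlation
undefined (NaN, warned). ESRI ASCII grids are written at `%.17g` so
doubles round-trip exactly; district labels round-trip as integers.

## Known limitations

- The maxent variant is linear/quadratic only; species with sharply
  thresholded responses will be under-fit relative to hinge-feature
  implementations.
- Encounter extrapolation assumes rates depend only on versant and
  altitude band within the range — no seasonal, land-cover, or
  distance-to-water structure.
- OLS with Gaussian errors is assumed throughout the calibration;
  count-model alternatives (Poisson/negative-binomial GLM) are not
  implemented.
- No CRS handling: all rasters must share shape, origin, and cell size
  already.
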