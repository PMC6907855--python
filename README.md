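# vipermass

Mass-action modelling of snakebite incidence from venomous-snake
distribution, field encounter rates, and rural census data.

Snakebite envenoming concentrates in rural tropical communities, where
incidence records are often incomplete. When the bites are dominated by a
single abundant species — such as the terciopelo pit viper (*Bothrops
asper*) in Central America — the spatial pattern of incidence can be
modelled from first principles: under the law of mass action, encounters
between a randomly mixing exposed population and a snake population are
proportional to the product of their sizes, so the yearly caseload of
district *i* is

```
I_i = alpha + theta * F_i * S_i
```

where `S_i` is the rural (exposed) population, `F_i` the district-averaged
encounter frequency with the snake (individuals per person-hour of
standardized active search), `theta` the conditional probability that an
encounter produces a bite, and `alpha` an intercept that zeroes the mean
residual — which makes the summed fitted incidence reproduce the reported
national caseload exactly for any intercept model.

The package implements the full chain needed to calibrate this model:

- **`vipermass.synth`** — synthetic landscapes (autocorrelated covariates,
  ridge-divided elevation, contiguous districts), occurrences from a known
  log-linear suitability, Poisson survey counts, log-normal census, and
  incidence with known `theta`/`alpha`, so the pipeline is testable end to
  end with no external data.
- **`vipermass.niche`** — a presence-background maximum-entropy species
  distribution model (Gibbs distribution over background cells, linear +
  quadratic features, L1 penalty), AUC evaluation against random
  pseudo-absence points, zero-omission/maximum-area thresholding, and
  altitude masking (the terciopelo's ceiling is 1200 m a.s.l.).
- **`vipermass.encounter`** — effort-weighted encounter rates per
  (versant × altitude band) stratum, extrapolation over the predicted
  range, and district-mean encounter frequencies.
- **`vipermass.incidence`** — OLS calibration of five candidate incidence
  structures, AIC comparison, 99% confidence/prediction bands, residual
  diagnostics, outlier-district flags, and a multi-species extension
  `I_i = alpha + sum_j theta_j * F_j,i * S_i`.
- **`vipermass.pipeline` / CLI `vipermass`** — orchestration with
  deterministic seeding and plain-text I/O (ESRI ASCII grids, headed CSV).

## Worked example

Run the whole pipeline on a synthetic study (simulate → distribution
model → encounter extrapolation → model comparison):

```sh
$ vipermass run --seed 7 --out runs/demo
AUC = 0.915; pooled rate = 0.1208; best model = 1; theta_hat = 0.0009589; R^2 = 0.757
report: runs/demo/run_report.json
```

The synthetic truth behind this run has `theta = 1e-3`, `alpha = 0.47`,
and stratum encounter rates that pool to about 0.15 snakes per
person-hour. The one-line summary says the fitted distribution model
separates presences from background well (AUC 0.92 against a random
baseline of 0.5), the survey-pooled national encounter rate is 0.12
snakes per person-hour, and among the five candidate regression
structures the mass-action model (Model 1) attains the lowest AIC,
recovering the bite-per-encounter probability to within 5% of truth
(`theta_hat = 9.6e-4`) and explaining 76% of the district variance.
`runs/demo/model_comparison.csv` holds the comparison table; the first
rows of this run:

```
model,structure,r_squared,aic,national_incidence,...
1,I = alpha + theta*F*S,0.757,15.03,22.52,...
2,I = theta*F*S,0.117,51.70,10.23,...   (no intercept: total not anchored)
3,I = alpha + theta*S,0.056,55.71,22.52,...
```

Note that every intercept model reports the same national incidence
(22.52 cases/year, the observed total): with an intercept, OLS residuals
sum to zero, so the fitted total is anchored to the reported total — only
the no-intercept Model 2 drifts. Per-district predictions with 99%
prediction bands and under/over-estimation flags are in
`runs/demo/district_predictions.csv`.

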