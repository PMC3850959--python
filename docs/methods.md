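# Methods

`miburden` estimates national cancer incidence indirectly, from the
mortality-to-incidence (MI) ratio. Cancer registries cover only a small,
unrepresentative fraction of many national populations, but a nationally
representative mortality survey may exist. The method learns the MI ratio
from registries (which record both cases and deaths), applies it to national
mortality rates, and propagates all uncertainty through a joint Bayesian
model.

## Data and age grid

All tables use a fixed 19-group age grid: 0, 1–4, 5–9, …, 80–84, 85+
(index `i = 1..19`). Inputs per stratum (sex × urban/rural):

- **Registry tables** (one per registry `j = 1..n`): person-years,
  incident cases, and deaths by age group.
- **National mortality table**: deaths and person-years by age group from a
  representative death survey (NDS).
- **National population** by age group, used to convert predicted rates to
  case counts.

## Joint model

Three linked Poisson regressions share parameters:

- Registry incidence:  `cases_ij ~ Poisson(exp(alpha_i + u_j) * PY_ij)`
- Registry mortality:  `deaths_ij ~ Poisson(exp(alpha_i + u_j + beta_i + v_j) * PY_ij)`
- National mortality:  `deaths_i ~ Poisson(exp(gamma_i) * PY_i)`

`alpha_i` is the log registry incidence rate, `exp(beta_i)` the age-specific
MI ratio, `gamma_i` the log national mortality rate. `u_j` and `v_j` are
registry random intercepts for incidence level and MI level
(`u_j ~ N(0, sigma_u^2)`, `v_j ~ N(0, sigma_v^2)`).

National incidence is predicted per posterior draw as
`exp(gamma_i - beta_i) * population_i`: national mortality divided by the
registry-estimated MI ratio.

### Age smoothing

Each of `alpha`, `beta`, `gamma` is an O'Sullivan penalized spline in
mixed-model form over the scaled age index `x_i = (i - 10) / 19`:

```
f(x_i) = phi_0 + phi_1 x_i + sum_k Z_ik psi_k
```

`Z` is built from a cubic B-spline basis with interior knots at ages 45,
55, 65 and 75 (mapped to the age groups containing them), transformed so
that the exact integrated-squared-second-derivative penalty becomes an
i.i.d. Gaussian prior on the `psi_k` (`K = 6` columns). Priors:
`phi ~ N(0, 10^4)`, `psi_k ~ N(0, sigma^2)` per curve, and all precisions
`1/sigma^2 ~ Gamma(0.001, 0.001)`. Sampling uses the log-variance
parametrization with the Jacobian-corrected prior density.

### MI ≤ 1 constrained variant

For comparison, a variant forces every MI ratio below one by modelling the
spline on the logit scale: `MI_i = expit(eta_i)` with `eta` given the same
spline structure, i.e. `beta_i = log(expit(eta_i))`.

## Inference

The posterior is sampled with the affine-invariant ensemble sampler
(`emcee`) using a mixture of differential-evolution moves (80% `DEMove`,
20% `DESnookerMove`); walkers are initialized in a tight Gaussian ball
around the posterior mode found by L-BFGS-B with the analytic gradient.
Two schedules are provided:

- `profile="paper"`: 25 000 burn-in, thin 25, 25 000 sampling iterations
  (1000 retained draws per walker) — production schedule.
- `profile="fast"`: 5 000 / 50 / 5 000 (100 per walker) — examples,
  smoke tests, acceptance targets.

Convergence is assessed by split-R̂ and effective sample size computed over
walkers (via `arviz`); R̂ > 1.05 raises a `RuntimeWarning`, not an error,
because ensemble walkers are not independent chains and the threshold is
advisory.

### Initialization of the constrained fit

The likelihood is nearly flat along the ridge that trades the common level
of `beta` against a shared shift in the `v_j` (only the shrinkage prior on
`v` identifies the split). From a cold start the constrained optimizer can
settle on the MI → 1 end of this ridge with all `v_j` compensating. The
constrained MAP therefore also warm-starts from the unconstrained MAP with
its `beta` curve mapped through the logit and projected back onto the
spline span, keeping whichever mode scores higher.

### Weak identifiability and the recovery harness

For the same reason, the fitted `beta` recovers the generative value only
up to the realized mean of the `v_j` (standard deviation
`sigma_v / sqrt(n)`, about 0.063 at `sigma_v = 0.2`, `n = 10`). This is a
property of the model, not a bug: with finitely many registries the "true"
average MI and the average registry effect cannot be separated. The
synthetic-data generator therefore offers `center_random_effects=True`,
which removes the sample mean of the drawn `u_j` and `v_j` so that
recovery studies measure estimation error against an exactly identified
truth. Analyses of real data are unaffected.

## Estimation outputs

All quantities are computed **per posterior draw** and then summarized
(mean and equal-tailed 2.5–97.5 percentile interval); transforming
posterior summaries instead would bias every nonlinear quantity.

- Age-specific MI ratios `exp(beta_i)`, and crude MI defined as the ratio
  of summed national deaths to summed predicted national cases (ratio of
  sums, not mean of ratios).
- National incident cases `exp(gamma_i - beta_i) * population_i`.
- World age-standardized rate (ASR): `100000 * sum_i rate_i * w_i` with
  the Segi world standard weights.
- Urban + rural (or other strata) combinations add counts draw-wise,
  assuming independent posteriors (strata are fitted independently).

Reporting conventions: MI to 2 decimals, rates to 1 decimal, case counts
in thousands to 1 decimal.

## Sensitivity analyses and validation

- **Leave-one-registry-out**: refit excluding each registry; report the
  percent change in total estimated cases.
- **Constrained comparison**: unconstrained vs MI ≤ 1 fit.
- **Age restriction**: refit on ages ≥ 20 with the spline basis rebuilt on
  the truncated grid.
- **NDS-overlap MI**: re-estimate MI using incidence only from registries
  flagged as covering death-survey areas, paired directly with NDS
  mortality (`deaths_i ~ Poisson(exp(alpha_i + beta_i) * PY_i)`); the
  exact likelihood wiring for this check is underdetermined and this is
  one documented, reasonable choice.
- **Internal validation**: estimated cases = observed deaths / MI draw,
  summed over ages, compared with a registry's observed cases.

## Verification

- The log posterior is checked term-by-term against an independent
  `scipy.stats` implementation, and the analytic gradient against central
  differences.
- A tensor-grid quadrature oracle for a reduced (1 age group, 1 registry,
  fixed hyperparameters) model pins the sampler's posterior means and
  interval widths.
- Simulation-based calibration: across replicated synthetic datasets the
  95% intervals for age-specific MI cover an age-varying truth at close to
  nominal rate (a constant-MI truth is deliberately avoided there: it
  coincides with the spline's shrinkage target and trivially over-covers).
- Five seeded recovery targets (`scripts/acceptance.py`) check the crude
  MI is recovered within ±0.03 at anchor values 0.74, 0.61, 0.93, 0.26
  and 0.69 spanning high- and low-fatality sites.

## Limitations

- Registries are assumed exchangeable given `u_j, v_j`; no covariates
  explain between-registry differences.
- The NDS mortality rates are taken at face value (no under-reporting
  adjustment beyond what the survey itself applied).
- Strata are modelled independently; no borrowing across sex or location.
- MCMC schedules trade accuracy for time; the fast profile can show
  R̂ up to ~1.1 on hard strata. Use the paper profile for reported results.
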