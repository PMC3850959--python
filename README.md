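# miburden

Bayesian indirect estimation of national cancer incidence from
mortality-to-incidence (MI) ratios.

Cancer registries often cover only a small, unrepresentative slice of a
country, while a representative national death survey measures mortality
alone. `miburden` fits a joint hierarchical model to both sources: three
linked Poisson regressions share age-smoothed curves for registry incidence,
the registry-level MI ratio, and national mortality, with registry random
effects capturing between-registry heterogeneity. National incidence is then
predicted per posterior draw as national mortality divided by the MI ratio,
so every output — age-specific and crude MI ratios, incident case counts,
world age-standardized rates (ASR) — carries a full 95% credible interval.

See [docs/methods.md](docs/methods.md) for the model, priors, sampler, and
validation strategy.

## Quick start

```python
import numpy as np
import miburden as mb

basis = mb.build_basis(mb.AgeGrid())      # 19 age groups, O'Sullivan spline

# registries: person-years, incident cases and deaths per age group
registries = [mb.RegistryTable("R1", py1, cases1, deaths1),
              mb.RegistryTable("R2", py2, cases2, deaths2)]
national = mb.NationalMortalityTable(nds_deaths, nds_person_years)

samples = mb.fit(registries, national, basis, profile="paper", seed=1)

est = mb.estimate_burden(samples, national_population,
                         site="All sites", stratum="urban")
print(est.table_row())   # crude MI, ASR, cases (thousands), each with 95% CI
```

`examples/` contains four narrative scripts. `examples/01_simulate_and_fit.py`
generates a synthetic stratum with true crude MI 0.74 and recovers it:

```text
$ python examples/01_simulate_and_fit.py
generated 10 registries; observed crude MI by registry: [0.783, 0.74, 0.749, 0.7] ...
true crude MI          : 0.740
posterior mean crude MI: 0.746  (95% CI 0.686-0.813)
  MI at ages  15-19: 0.766
  MI at ages  40-44: 0.758
  MI at ages  65-69: 0.749
  MI at ages    85+: 0.743
```

The others cover urban/rural burden combination (`02`), leave-one-out and
constrained-fit sensitivity analyses (`03`), and internal validation against
a held-out registry (`04`).

## Testing

```bash
python -m pytest            # full suite, ~7 min (MCMC-heavy)
python -m pytest tests -k "not acceptance"   # fast structural suite
```

The suite includes exact identities on fixed draws, a term-by-term
`scipy.stats` oracle for the log posterior, a quadrature oracle for the
sampler, parameter-recovery checks, and a smoke-scale coverage study.

## Layout

- `src/miburden/` — the library (age grid, IO, spline basis, generator,
  model + MCMC, estimation, sensitivity analyses)
- `tests/` — pytest suite; `tests/test_acceptance.py` holds the
  acceptance-criteria tests
- `scripts/acceptance.py` — recovery-target runner
- `examples/` — narrative example scripts
- `docs/methods.md` — methods note
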