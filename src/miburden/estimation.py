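"""From posterior draws to reported burden quantities.

Every quantity is computed draw by draw and only then summarized (posterior
mean and equal-tailed 2.5-97.5% interval), so nonlinear maps such as
exp(gamma - beta) or the deaths/incidence ratio are never applied to a
posterior summary.

Conventions follow cancer-registration practice: national incidence in age
group i is exp(gamma_i - beta_i) x national population; the all-ages
("crude") MI ratio is the ratio of summed national deaths to summed national
incident cases (a ratio of sums, not a mean of age-specific ratios); the
age-standardized rate (ASR) uses the Segi world standard per 100 000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import StandardPopulation, world_standard
from .fit import PosteriorSamples


@dataclass(frozen=True)
class CredibleSummary:
    """Posterior mean with equal-tailed 95% credible interval."""

    mean: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_draws(cls, draws: np.ndarray, ci: float = 0.95) -> "CredibleSummary":
        draws = np.asarray(draws, dtype=float)
        tail = 100.0 * (1.0 - ci) / 2.0
        lo, hi = np.percentile(draws, [tail, 100.0 - tail])
        return cls(mean=float(draws.mean()), ci_low=float(lo), ci_high=float(hi))

    def round(self, ndigits: int) -> tuple[float, float, float]:
        return (
            round(self.mean, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def _align_population(samples: PosteriorSamples, population: np.ndarray) -> np.ndarray:
    population = np.asarray(population, dtype=float)
    n_ages = samples.basis.n_ages
    if population.shape == (n_ages,):
        return population
    if population.shape == (19,):
        return population[samples.basis.age_indices - 1]
    raise ValueError(
        f"population must cover the fitted age groups (need {n_ages} rows, "
        f"got shape {population.shape})"
    )


def national_incidence_draws(
    samples: PosteriorSamples, population: np.ndarray
) -> np.ndarray:
    """Per-draw national incident cases by age: exp(gamma - beta) x population."""
    pop = _align_population(samples, population)
    rate = np.exp(samples.gamma_draws - samples.beta_draws)
    return rate * pop


def national_deaths_draws(
    samples: PosteriorSamples, population: np.ndarray
) -> np.ndarray:
    """Per-draw national cancer deaths by age: exp(gamma) x population."""
    pop = _align_population(samples, population)
    return np.exp(samples.gamma_draws) * pop


def crude_mi_draws(
    samples: PosteriorSamples,
    national_person_years: np.ndarray,
) -> np.ndarray:
    """All-ages MI per draw: sum of national deaths over national incidence."""
    py = _align_population(samples, np.asarray(national_person_years, float))
    deaths = np.exp(samples.gamma_draws) * py
    cases = np.exp(samples.gamma_draws - samples.beta_draws) * py
    return deaths.sum(axis=1) / cases.sum(axis=1)


def mi_ratio_summary(
    samples: PosteriorSamples,
    national_person_years: np.ndarray | None = None,
    registries=None,
    weights: str = "national",
) -> dict:
    """Age-specific and all-ages MI-ratio posterior summaries.

    ``weights`` selects the all-ages denominator: "national" (default) uses
    the national mortality curve exp(gamma) with the supplied person-years;
    "registry" weights by summed registry person-years instead.
    """
    mi = samples.mi_draws
    per_age = [CredibleSummary.from_draws(mi[:, i]) for i in range(mi.shape[1])]
    if weights == "national":
        if national_person_years is None:
            raise ValueError("national weighting needs national_person_years")
        crude = crude_mi_draws(samples, national_person_years)
    elif weights == "registry":
        if not registries:
            raise ValueError("registry weighting needs the registry tables")
        py = np.sum([t.population for t in registries], axis=0)
        py = _align_population(samples, py)
        deaths = np.exp(samples.gamma_draws) * py
        cases = np.exp(samples.gamma_draws - samples.beta_draws) * py
        crude = deaths.sum(axis=1) / cases.sum(axis=1)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    return {
        "per_age": per_age,
        "crude": CredibleSummary.from_draws(crude),
        "crude_draws": crude,
    }


def asr_draws(
    rate_draws: np.ndarray, standard: StandardPopulation, age_indices: np.ndarray | None = None
) -> np.ndarray:
    """Per-draw ASR per 100 000 = 1e5 x sum_i w_i rate_i."""
    rate_draws = np.asarray(rate_draws, dtype=float)
    w = standard.weights
    if age_indices is not None:
        w = w[np.asarray(age_indices) - 1]
    if rate_draws.shape[-1] != w.shape[0]:
        raise ValueError(
            f"rate draws cover {rate_draws.shape[-1]} age groups but the "
            f"standard has {w.shape[0]} weights"
        )
    return 1e5 * rate_draws @ w


def age_standardized_rate(
    rate_draws: np.ndarray,
    standard: StandardPopulation,
    age_indices: np.ndarray | None = None,
) -> CredibleSummary:
    """ASR per 100 000, summarized over draws."""
    return CredibleSummary.from_draws(asr_draws(rate_draws, standard, age_indices))


@dataclass
class BurdenEstimate:
    """Posterior burden quantities for one site and stratum.

    Carries the per-draw arrays so strata can be combined draw-wise; the
    summary accessors apply the table conventions (MI to 2 decimals, rates
    and case counts in thousands to 1 decimal).
    """

    site: str
    stratum: str
    population: np.ndarray            # national population by fitted age group
    mi_age_draws: np.ndarray          # (n_draws, n_ages)
    incidence_rate_draws: np.ndarray  # per person-year, (n_draws, n_ages)
    deaths_rate_draws: np.ndarray     # per person-year, (n_draws, n_ages)
    standard: StandardPopulation
    age_indices: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.mi_age_draws.shape[0]

    @property
    def cases_draws(self) -> np.ndarray:
        """Total incident cases per draw."""
        return (self.incidence_rate_draws * self.population).sum(axis=1)

    @property
    def deaths_draws(self) -> np.ndarray:
        return (self.deaths_rate_draws * self.population).sum(axis=1)

    @property
    def crude_mi_draws(self) -> np.ndarray:
        return self.deaths_draws / self.cases_draws

    @property
    def asr_draws(self) -> np.ndarray:
        return asr_draws(self.incidence_rate_draws, self.standard, self.age_indices)

    # -- summaries -----------------------------------------------------------

    def mi_per_age(self) -> list[CredibleSummary]:
        return [
            CredibleSummary.from_draws(self.mi_age_draws[:, i])
            for i in range(self.mi_age_draws.shape[1])
        ]

    def crude_mi(self) -> CredibleSummary:
        return CredibleSummary.from_draws(self.crude_mi_draws)

    def rate_per_age(self) -> list[CredibleSummary]:
        return [
            CredibleSummary.from_draws(1e5 * self.incidence_rate_draws[:, i])
            for i in range(self.incidence_rate_draws.shape[1])
        ]

    def asr(self) -> CredibleSummary:
        return CredibleSummary.from_draws(self.asr_draws)

    def cases_thousands(self) -> CredibleSummary:
        return CredibleSummary.from_draws(self.cases_draws / 1e3)

    def table_row(self) -> dict:
        mi = self.crude_mi().round(2)
        asr = self.asr().round(1)
        cases = self.cases_thousands().round(1)
        return {
            "site": self.site,
            "stratum": self.stratum,
            "mi": mi[0], "mi_lo": mi[1], "mi_hi": mi[2],
            "asr": asr[0], "asr_lo": asr[1], "asr_hi": asr[2],
            "cases_1000s": cases[0], "cases_lo": cases[1], "cases_hi": cases[2],
        }


def estimate_burden(
    samples: PosteriorSamples,
    population: np.ndarray,
    standard: StandardPopulation | None = None,
    site: str = "",
    stratum: str = "",
) -> BurdenEstimate:
    """Assemble the draw-wise burden estimate for one fitted stratum."""
    pop = _align_population(samples, population)
    return BurdenEstimate(
        site=site,
        stratum=stratum,
        population=pop,
        mi_age_draws=samples.mi_draws,
        incidence_rate_draws=np.exp(samples.gamma_draws - samples.beta_draws),
        deaths_rate_draws=np.exp(samples.gamma_draws),
        standard=standard or world_standard(),
        age_indices=samples.basis.age_indices,
    )


def combine_strata(estimates: list[BurdenEstimate]) -> BurdenEstimate:
    """Combine independently fitted strata (e.g. urban + rural) draw-wise.

    Case and death counts add per draw; combined rates divide the pooled
    counts by the pooled population, from which the combined ASR and crude
    MI are recomputed.
    """
    if not estimates:
        raise ValueError("nothing to combine")
    sites = {e.site for e in estimates}
    if len(sites) > 1:
        raise ValueError(f"cannot combine different sites {sorted(sites)}")
    n_draws = {e.n_draws for e in estimates}
    if len(n_draws) > 1:
        raise ValueError("strata must have the same number of draws")
    shapes = {e.population.shape for e in estimates}
    if len(shapes) > 1:
        raise ValueError("strata must cover the same age groups")

    pop = np.sum([e.population for e in estimates], axis=0)
    cases_by_age = np.sum(
        [e.incidence_rate_draws * e.population for e in estimates], axis=0
    )
    deaths_by_age = np.sum(
        [e.deaths_rate_draws * e.population for e in estimates], axis=0
    )
    rate = cases_by_age / pop
    deaths_rate = deaths_by_age / pop
    return BurdenEstimate(
        site=estimates[0].site,
        stratum="+".join(e.stratum for e in estimates),
        population=pop,
        mi_age_draws=deaths_rate / rate,
        incidence_rate_draws=rate,
        deaths_rate_draws=deaths_rate,
        standard=estimates[0].standard,
        age_indices=estimates[0].age_indices,
    )


__all__ = [
    "BurdenEstimate",
    "CredibleSummary",
    "age_standardized_rate",
    "asr_draws",
    "combine_strata",
    "crude_mi_draws",
    "estimate_burden",
    "mi_ratio_summary",
    "national_deaths_draws",
    "national_incidence_draws",
]
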