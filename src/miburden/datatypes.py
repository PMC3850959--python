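"""Domain containers: strata, sites, and the count tables the model consumes.

All per-age vectors are numpy arrays of length 19 ordered by the age-grid
index i = 1..19.  Models are fitted independently per (site, sex, location)
stratum, so each table carries one stratum of one site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .agegrid import AgeGrid

N_AGE = 19


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Location(str, enum.Enum):
    URBAN = "urban"
    RURAL = "rural"


@dataclass(frozen=True)
class Stratum:
    """One of the four sex x urban/rural combinations fitted independently."""

    sex: Sex
    location: Location

    @staticmethod
    def all() -> list["Stratum"]:
        return [Stratum(s, l) for s in Sex for l in Location]

    def __str__(self) -> str:
        return f"{self.sex.value}/{self.location.value}"


@dataclass(frozen=True)
class SiteCode:
    """A cancer site with its ICD-10 code ranges.

    ``valid_sex`` restricts sex-specific sites (breast, cervix, ovary,
    prostate); None means both sexes.
    """

    name: str
    icd10: tuple[str, ...]
    valid_sex: Sex | None = None


#: The 14 sites reported in the national burden tables, plus all sites combined.
STANDARD_SITES: tuple[SiteCode, ...] = (
    SiteCode("Nasopharynx", ("C11",)),
    SiteCode("Esophagus", ("C15",)),
    SiteCode("Stomach", ("C16",)),
    SiteCode("Colorectal", ("C18-C21",)),
    SiteCode("Liver", ("C22",)),
    SiteCode("Pancreas", ("C25",)),
    SiteCode("Lung", ("C33-C34",)),
    SiteCode("Bone", ("C40-C41",)),
    SiteCode("Breast", ("C50",), Sex.FEMALE),
    SiteCode("Cervix", ("C53",), Sex.FEMALE),
    SiteCode("Ovary", ("C56",), Sex.FEMALE),
    SiteCode("Prostate", ("C61",), Sex.MALE),
    SiteCode("CNS", ("C70-C72",)),
    SiteCode("Lymphoma", ("C81-C85", "C88", "C90", "C96")),
    SiteCode("All sites", ("C00-C97",)),
)


def site_by_name(name: str) -> SiteCode:
    for s in STANDARD_SITES:
        if s.name == name:
            return s
    raise KeyError(f"unknown site {name!r}")


def _as_counts(x, what: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (N_AGE,):
        raise ValueError(f"{what} must have length {N_AGE}, got shape {a.shape}")
    if np.any(a < 0):
        raise ValueError(f"{what} must be non-negative")
    if not np.allclose(a, np.round(a)):
        raise ValueError(f"{what} must be integer counts")
    return np.round(a).astype(np.int64)


def _as_positive(x, what: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (N_AGE,):
        raise ValueError(f"{what} must have length {N_AGE}, got shape {a.shape}")
    if np.any(a <= 0) or not np.all(np.isfinite(a)):
        raise ValueError(f"{what} must be strictly positive and finite")
    return a


@dataclass(frozen=True)
class RegistryTable:
    """Observed counts for one registry, one site, one stratum.

    population is person-years at risk; incident_cases and deaths are
    non-negative integer counts, one entry per age group.
    """

    registry_id: str
    population: np.ndarray
    incident_cases: np.ndarray
    deaths: np.ndarray
    nds_overlap: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "population", _as_positive(self.population, "population"))
        object.__setattr__(
            self, "incident_cases", _as_counts(self.incident_cases, "incident_cases")
        )
        object.__setattr__(self, "deaths", _as_counts(self.deaths, "deaths"))

    def crude_mi(self) -> float:
        """All-ages deaths / all-ages cases; nan when no cases registered."""
        cases = int(self.incident_cases.sum())
        if cases == 0:
            return float("nan")
        return float(self.deaths.sum()) / cases


@dataclass(frozen=True)
class NationalMortalityTable:
    """National death-survey deaths and person-years by age, one site/stratum."""

    deaths: np.ndarray
    person_years: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "deaths", _as_counts(self.deaths, "deaths"))
        object.__setattr__(
            self, "person_years", _as_positive(self.person_years, "person_years")
        )

    def rates(self) -> np.ndarray:
        return self.deaths / self.person_years


@dataclass(frozen=True)
class PopulationTable:
    """National population by age for each stratum."""

    counts: dict[Stratum, np.ndarray]
    national_total: float | None = None

    def __post_init__(self) -> None:
        clean = {s: _as_positive(v, f"population[{s}]") for s, v in self.counts.items()}
        object.__setattr__(self, "counts", clean)
        if self.national_total is not None:
            total = sum(float(v.sum()) for v in clean.values())
            if not np.isclose(total, self.national_total, rtol=1e-9):
                raise ValueError(
                    f"stratum populations sum to {total:.0f}, expected national "
                    f"total {self.national_total:.0f}"
                )

    def __getitem__(self, stratum: Stratum) -> np.ndarray:
        return self.counts[stratum]


@dataclass(frozen=True)
class StandardPopulation:
    """Standard-population age weights for direct standardization.

    Weights are normalized to sum to one on construction.
    """

    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_AGE,):
            raise ValueError(f"weights must have length {N_AGE}")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        object.__setattr__(self, "weights", w / w.sum())


# Segi world standard population expanded to the 19-group grid (the 0-4
# band split 2 400 / 9 600 as in cancer-registry practice); totals 100 000.
_SEGI = np.array(
    [2400, 9600, 10000, 9000, 9000, 8000, 8000, 6000, 6000, 6000, 6000,
     5000, 4000, 4000, 3000, 2000, 1000, 500, 500],
    dtype=float,
)


def world_standard() -> StandardPopulation:
    """The Segi world standard used for 'World age-standardized' rates."""
    return StandardPopulation(_SEGI, name="world (Segi)")


__all__ = [
    "AgeGrid",
    "Location",
    "N_AGE",
    "NationalMortalityTable",
    "PopulationTable",
    "RegistryTable",
    "Sex",
    "SiteCode",
    "StandardPopulation",
    "STANDARD_SITES",
    "Stratum",
    "site_by_name",
    "world_standard",
]
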