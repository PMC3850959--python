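"""Dataset quality report: crude per-registry MI ratios and basic flags.

Report-only: inputs are never mutated.  The crude mortality-to-incidence
ratio per registry is all-ages deaths over all-ages cases, the registry-level
quality indicator conventionally reported alongside morphological
verification and death-certificate-only percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datatypes import NationalMortalityTable, PopulationTable, RegistryTable, Stratum


@dataclass(frozen=True)
class RegistryCheck:
    registry_id: str
    site: str
    stratum: str
    total_cases: int
    total_deaths: int
    crude_mi: float
    flags: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[RegistryCheck, ...]
    empty_strata: tuple[str, ...] = ()

    @property
    def flagged(self) -> tuple[RegistryCheck, ...]:
        return tuple(c for c in self.checks if c.flags)


def validate_dataset(
    registries: dict[tuple[str, Stratum], list[RegistryTable]],
    national: dict[tuple[str, Stratum], NationalMortalityTable] | None = None,
    populations: PopulationTable | None = None,
) -> ValidationReport:
    """Compute per-registry crude MI ratios and flag suspect entries.

    Flags: ``mi>1`` when deaths exceed cases; ``mi_undefined`` when a
    registry recorded deaths but no cases.  Strata present in the national
    mortality table but without any registry data are listed as empty.
    """
    checks = []
    for (site, stratum), tables in sorted(registries.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        for t in tables:
            cases = int(t.incident_cases.sum())
            deaths = int(t.deaths.sum())
            mi = t.crude_mi()
            flags: list[str] = []
            if math.isnan(mi):
                if deaths > 0:
                    flags.append("mi_undefined")
            elif mi > 1:
                flags.append("mi>1")
            checks.append(
                RegistryCheck(
                    registry_id=t.registry_id,
                    site=site,
                    stratum=str(stratum),
                    total_cases=cases,
                    total_deaths=deaths,
                    crude_mi=mi,
                    flags=tuple(flags),
                )
            )
    empty = []
    if national is not None:
        for key in sorted(national, key=lambda k: (k[0], str(k[1]))):
            if key not in registries or not registries[key]:
                empty.append(f"{key[0]} {key[1]}")
    return ValidationReport(checks=tuple(checks), empty_strata=tuple(empty))


__all__ = ["RegistryCheck", "ValidationReport", "validate_dataset"]
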