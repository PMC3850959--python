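"""Delimited-text readers and writers for the count tables, plus run config.

All tables travel as one long-format CSV with a header row; lines starting
with '#' are metadata comments (seed, config hash) and are skipped on read.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agegrid import AGE_GROUP_LABELS, AgeGrid
from .datatypes import (
    N_AGE,
    Location,
    NationalMortalityTable,
    RegistryTable,
    Sex,
    Stratum,
)

_REGISTRY_COLS = [
    "registry_id", "site", "sex", "location", "age_group",
    "population", "cases", "deaths",
]
_NATIONAL_COLS = ["site", "sex", "location", "age_group", "deaths", "person_years"]


class DataFormatError(ValueError):
    """A structural problem in an input table (missing rows, bad labels)."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _check_age_groups(sub: pd.DataFrame, context: str) -> pd.DataFrame:
    labels = list(sub["age_group"].astype(str))
    bad = sorted(set(labels) - set(AGE_GROUP_LABELS))
    if bad:
        raise DataFormatError(f"{context}: unknown age group(s) {bad}")
    if len(labels) != len(set(labels)):
        raise DataFormatError(f"{context}: duplicated age groups")
    missing = [g for g in AGE_GROUP_LABELS if g not in labels]
    if missing:
        raise DataFormatError(f"{context}: missing age group(s) {missing}")
    order = {g: k for k, g in enumerate(AGE_GROUP_LABELS)}
    return sub.sort_values("age_group", key=lambda s: s.map(order))


def read_registry_tables(path) -> dict[tuple[str, Stratum], list[RegistryTable]]:
    """Read a long-format registry file into tables keyed by (site, stratum).

    Each (registry, site, sex, location) block must contain exactly the 19
    standard age groups.  Returns {(site, stratum): [RegistryTable, ...]}.
    """
    df = _read_csv(path)
    missing = set(_REGISTRY_COLS) - set(df.columns)
    if missing:
        raise DataFormatError(f"registry file missing columns {sorted(missing)}")
    out: dict[tuple[str, Stratum], list[RegistryTable]] = {}
    has_flag = "nds_overlap" in df.columns
    keys = ["site", "sex", "location", "registry_id"]
    for (site, sex, location, rid), sub in df.groupby(keys, sort=True):
        context = f"registry {rid!r} site {site!r} {sex}/{location}"
        sub = _check_age_groups(sub, context)
        stratum = Stratum(Sex(sex), Location(location))
        table = RegistryTable(
            registry_id=str(rid),
            population=sub["population"].to_numpy(float),
            incident_cases=sub["cases"].to_numpy(float),
            deaths=sub["deaths"].to_numpy(float),
            nds_overlap=bool(sub["nds_overlap"].iloc[0]) if has_flag else False,
        )
        out.setdefault((str(site), stratum), []).append(table)
    return out


def write_registry_tables(
    path,
    tables: dict[tuple[str, Stratum], list[RegistryTable]],
    *,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    rows = []
    for (site, stratum), regs in tables.items():
        for t in regs:
            for k, label in enumerate(AGE_GROUP_LABELS):
                rows.append({
                    "registry_id": t.registry_id,
                    "site": site,
                    "sex": stratum.sex.value,
                    "location": stratum.location.value,
                    "age_group": label,
                    "population": t.population[k],
                    "cases": int(t.incident_cases[k]),
                    "deaths": int(t.deaths[k]),
                    "nds_overlap": t.nds_overlap,
                })
    _write_with_header(path, pd.DataFrame(rows), seed=seed, config_hash=config_hash)


def read_national_mortality(path) -> dict[tuple[str, Stratum], NationalMortalityTable]:
    """Read national death-survey mortality keyed by (site, stratum)."""
    df = _read_csv(path)
    missing = set(_NATIONAL_COLS) - set(df.columns)
    if missing:
        raise DataFormatError(f"national mortality file missing columns {sorted(missing)}")
    out: dict[tuple[str, Stratum], NationalMortalityTable] = {}
    for (site, sex, location), sub in df.groupby(["site", "sex", "location"], sort=True):
        context = f"national mortality site {site!r} {sex}/{location}"
        sub = _check_age_groups(sub, context)
        table = NationalMortalityTable(
            deaths=sub["deaths"].to_numpy(float),
            person_years=sub["person_years"].to_numpy(float),
        )
        out[(str(site), Stratum(Sex(sex), Location(location)))] = table
    return out


def write_national_mortality(
    path,
    tables: dict[tuple[str, Stratum], NationalMortalityTable],
    *,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    rows = []
    for (site, stratum), t in tables.items():
        for k, label in enumerate(AGE_GROUP_LABELS):
            rows.append({
                "site": site,
                "sex": stratum.sex.value,
                "location": stratum.location.value,
                "age_group": label,
                "deaths": int(t.deaths[k]),
                "person_years": t.person_years[k],
            })
    _write_with_header(path, pd.DataFrame(rows), seed=seed, config_hash=config_hash)


def _write_with_header(path, df: pd.DataFrame, *, seed=None, config_hash=None) -> None:
    buf = _io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    if config_hash is not None:
        buf.write(f"# config_sha256={config_hash}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    sites: list[str] = field(default_factory=lambda: ["All sites"])
    strata: list[str] = field(
        default_factory=lambda: [str(s) for s in Stratum.all()]
    )
    mcmc_profile: str = "paper"          # "paper" or "fast"
    constrained: bool = False            # force MI <= 1 via logit spline
    min_age_years: float | None = None   # e.g. 20 to drop younger groups
    seed: int = 0
    registry_path: str = "registries.csv"
    national_path: str = "national_mortality.csv"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def sha256(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


__all__ = [
    "AnalysisConfig",
    "DataFormatError",
    "read_national_mortality",
    "read_registry_tables",
    "write_national_mortality",
    "write_registry_tables",
]
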