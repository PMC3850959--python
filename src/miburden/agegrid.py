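"""The standard 19-group age grid of cancer registration.

Ages are grouped as 0, 1-4, then five-year bands 5-9 ... 80-84, and 85+.
Internally every table is indexed by the 1-based group index ``i`` = 1..19;
the label vocabulary is closed.  Group midpoints (in years) are needed only
for spline-knot placement and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field


AGE_GROUP_LABELS: tuple[str, ...] = (
    "0",
    "1-4",
    "5-9",
    "10-14",
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85+",
)

# 0 -> 0.5, 1-4 -> 3, five-year bands -> band centre, open-ended 85+ -> 90.
_MIDPOINTS: tuple[float, ...] = (0.5, 3.0) + tuple(
    (lo + lo + 4) / 2 + 0.5 for lo in range(5, 85, 5)
) + (90.0,)


@dataclass(frozen=True)
class AgeGrid:
    """The fixed 19-group age grid.

    ``index(label)`` maps a label to the 1-based group index i;
    ``midpoint_age(i)`` returns the group's midpoint in years;
    ``group_containing(age)`` the 1-based index of the group an exact age
    falls in.
    """

    groups: tuple[str, ...] = field(default=AGE_GROUP_LABELS)

    def __post_init__(self) -> None:
        if self.groups != AGE_GROUP_LABELS:
            raise ValueError(
                "age grid must consist of the 19 standard groups "
                f"{AGE_GROUP_LABELS!r}"
            )

    @property
    def n_groups(self) -> int:
        return 19

    @property
    def indices(self) -> range:
        """1-based group indices i = 1..19."""
        return range(1, 20)

    def index(self, label: str) -> int:
        try:
            return self.groups.index(label) + 1
        except ValueError:
            raise ValueError(f"unknown age-group label {label!r}") from None

    def midpoint_age(self, i: int) -> float:
        if not 1 <= i <= 19:
            raise ValueError(f"age index must be in 1..19, got {i}")
        return _MIDPOINTS[i - 1]

    @property
    def midpoints(self) -> tuple[float, ...]:
        return _MIDPOINTS

    def group_containing(self, age_years: float) -> int:
        """1-based index of the group containing an exact age in years."""
        if age_years < 0:
            raise ValueError("age must be non-negative")
        if age_years < 1:
            return 1
        if age_years < 5:
            return 2
        if age_years >= 85:
            return 19
        return 3 + int((age_years - 5) // 5)

    def lower_bound(self, i: int) -> float:
        """Lower age bound (years) of group i."""
        bounds = (0.0, 1.0) + tuple(float(a) for a in range(5, 90, 5))
        if not 1 <= i <= 19:
            raise ValueError(f"age index must be in 1..19, got {i}")
        return bounds[i - 1]
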