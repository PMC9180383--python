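"""Core health-impact chain: exposure dose -> cancer risk -> expected deaths.

The chain is linear throughout.  For an age group *i*, region *j* and time
period *t*:

    risk[i,j]   = LADD[i,j] * CSF           (excess lifetime cancer risk)
    er[i,j,t]   = risk[i,j] * pop[i,j,t]    (expected people at risk)
    d[i,j,t]    = er[i,j,t] * mrisk         (expected cancer deaths)

LADD is the lifetime average daily dose in pg-TEQ/kg/day, CSF the cancer
slope factor per unit dose, and mrisk the complement of the all-cancer
survival rate.  Exposure is keyed by (age_group, region) only: dietary
patterns differ by age and region but are treated as constant over the
projection horizon.  Expected counts stay fractional; nothing is rounded
until report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .errors import ValidationError

__all__ = [
    "AgeGroup",
    "Region",
    "Period",
    "ExposureTable",
    "RiskTable",
    "RiskCoefficients",
    "PopulationTable",
    "compute_cancer_risk",
    "expected_at_risk",
    "expected_deaths",
    "mortality_risk_from_survival",
]


class AgeGroup(str, Enum):
    """The three population age bands used throughout the analysis."""

    CHILDREN = "children"          # ages 0-14, not in the labour force
    WORKING_AGE = "working_age"    # ages 15-64
    OLDER = "older"                # ages 65+

    @property
    def age_range(self) -> tuple[int, int | None]:
        return {"children": (0, 14), "working_age": (15, 64), "older": (65, None)}[self.value]


AGE_GROUP_IDS: tuple[str, ...] = tuple(g.value for g in AgeGroup)


@dataclass(frozen=True)
class Region:
    """A spatial unit; the national aggregate is a first-class region.

    The aggregate carries its own exposure coefficients and is never derived
    by summing sub-regions (regional dose profiles are heterogeneous, so the
    national monetized burden is not the sum of regional burdens).
    """

    id: str
    label: str = ""
    is_national: bool = False


@dataclass(frozen=True)
class Period:
    """A reporting interval; a single base year (e.g. 2020) is allowed."""

    id: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValidationError(
                f"period {self.id!r}: start_year {self.start_year} > end_year {self.end_year}",
                key=self.id,
            )

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def _require_index(data: pd.Series, names: tuple[str, ...], what: str) -> pd.Series:
    if not isinstance(data, pd.Series):
        raise ValidationError(f"{what}: expected a pandas Series, got {type(data).__name__}")
    if data.index.nlevels != len(names):
        raise ValidationError(
            f"{what}: expected index levels {names}, got {data.index.nlevels} level(s)"
        )
    data = data.copy()
    data.index = data.index.set_names(list(names))
    return data.astype(float)


def _check_complete(data: pd.Series, grid: pd.MultiIndex, what: str) -> None:
    missing = grid.difference(data.index)
    if len(missing) > 0:
        key = tuple(missing[0])
        raise ValidationError(f"{what}: missing cell {key}", key=key)


def _check_nonnegative(data: pd.Series, what: str) -> None:
    bad = data[data < 0]
    if not bad.empty:
        key = bad.index[0]
        key = tuple(key) if isinstance(key, tuple) else key
        raise ValidationError(f"{what}: negative value {bad.iloc[0]} at {key}", key=key)


@dataclass
class ExposureTable:
    """Lifetime average daily dose (pg-TEQ/kg/day) by (age_group, region)."""

    ladd: pd.Series
    flagged: frozenset = field(default_factory=frozenset)
    # ``flagged`` marks cells whose dose was back-derived from a published
    # risk figure rather than taken from a published dose figure.

    def __post_init__(self) -> None:
        self.ladd = _require_index(self.ladd, ("age_group", "region"), "ExposureTable")
        _check_nonnegative(self.ladd, "ExposureTable.ladd")

    @property
    def grid(self) -> pd.MultiIndex:
        return self.ladd.index


@dataclass
class RiskTable:
    """Excess lifetime cancer risk (probability) by (age_group, region)."""

    risk: pd.Series

    def __post_init__(self) -> None:
        self.risk = _require_index(self.risk, ("age_group", "region"), "RiskTable")
        _check_nonnegative(self.risk, "RiskTable.risk")
        bad = self.risk[self.risk > 1]
        if not bad.empty:
            raise ValidationError(
                f"RiskTable: risk {bad.iloc[0]} > 1 at {tuple(bad.index[0])}",
                key=tuple(bad.index[0]),
            )

    @property
    def grid(self) -> pd.MultiIndex:
        return self.risk.index


@dataclass(frozen=True)
class RiskCoefficients:
    """Cancer slope factor (per pg-TEQ/kg/day) and cancer mortality risk."""

    csf: float
    mortality_risk: float

    def __post_init__(self) -> None:
        if self.csf < 0:
            raise ValidationError(f"csf must be >= 0, got {self.csf}")
        if not 0.0 <= self.mortality_risk <= 1.0:
            raise ValidationError(
                f"mortality_risk must lie in [0, 1], got {self.mortality_risk}"
            )


@dataclass
class PopulationTable:
    """Person counts by (age_group, region, period); fractional counts allowed."""

    count: pd.Series

    def __post_init__(self) -> None:
        self.count = _require_index(
            self.count, ("age_group", "region", "period"), "PopulationTable"
        )
        _check_nonnegative(self.count, "PopulationTable.count")

    def slice_period(self, period_id: str) -> pd.Series:
        """Counts for one period, indexed by (age_group, region)."""
        if period_id not in self.count.index.get_level_values("period"):
            raise ValidationError(
                f"PopulationTable: period {period_id!r} absent", key=period_id
            )
        return self.count.xs(period_id, level="period")

    @property
    def period_ids(self) -> list[str]:
        return list(dict.fromkeys(self.count.index.get_level_values("period")))


def mortality_risk_from_survival(survival_rate: float) -> float:
    """Cancer mortality risk as the complement of the all-cancer survival rate."""
    if not 0.0 <= survival_rate <= 1.0:
        raise ValidationError(f"survival_rate must lie in [0, 1], got {survival_rate}")
    return 1.0 - survival_rate


def compute_cancer_risk(exposure: ExposureTable, coeffs: RiskCoefficients) -> RiskTable:
    """Excess lifetime cancer risk: dose times slope factor, cell by cell.

    The slope factor is common to all ages; age differentiation enters only
    through the dose table. The output is indexed exactly like the input.
    """
    risk = exposure.ladd * coeffs.csf
    return RiskTable(risk=risk)


def expected_at_risk(
    risk: RiskTable, population: PopulationTable, period: Period | str
) -> pd.Series:
    """Expected number of people at risk of cancer in one period.

    Returns ``risk[i,j] * pop[i,j,t]`` indexed by (age_group, region).
    """
    period_id = period.id if isinstance(period, Period) else period
    pop = population.slice_period(period_id)
    _check_complete(pop, risk.grid, f"PopulationTable[{period_id}]")
    er = risk.risk * pop.reindex(risk.grid)
    er.name = "expected_at_risk"
    return er


def expected_deaths(er: pd.Series, coeffs: RiskCoefficients) -> pd.Series:
    """Expected cancer deaths: at-risk counts times the cancer mortality risk."""
    d = er * coeffs.mortality_risk
    d.name = "expected_deaths"
    return d
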