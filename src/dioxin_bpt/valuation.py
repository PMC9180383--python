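"""Value-of-a-statistical-life transfer, discounting, and monetization.

A base-year VSL estimated from hedonic wage data is moved to the analysis
year in two steps: a wage-growth adjustment through the earnings elasticity,

    VSL_target = VSL_base * (1 + eps_W * %dW / 100),   %dW = 100*(W_t - W_b)/W_b

and a price-level deflation through the consumer price index,

    RVSL = nominal * CPI_base / CPI_target.

Both steps are multiplicative, so their order does not matter.  A per-age-
group VSL schedule over the projection periods is then built either by
annual geometric discounting averaged within each period, or supplied
verbatim (a published schedule).  Monetized mortality is simply
``deaths * VSL`` per cell.  All internal money values are USD; TWD inputs
are converted once on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, model_validator

from .core import Period, _check_nonnegative, _require_index
from .errors import ValidationError

__all__ = [
    "ValueTransferParams",
    "DiscountConvention",
    "DiscountSpec",
    "VSLSchedule",
    "MonetizedMortalityTable",
    "transfer_vsl_nominal",
    "deflate_vsl_real",
    "build_vsl_schedule",
    "monetize_deaths",
]


class ValueTransferParams(BaseModel):
    """Inputs for moving a VSL estimate across years.

    vsl_base is in millions of USD in the base year; wages are average
    monthly earnings in USD; CPIs share one index base; exchange_rate is
    TWD per USD (used only when ingesting TWD-denominated inputs).
    """

    vsl_base: float
    earnings_elasticity: float
    wage_base: float
    wage_target: float
    cpi_base: float
    cpi_target: float
    exchange_rate: float = 1.0

    @model_validator(mode="after")
    def _positive(self) -> "ValueTransferParams":
        for name in ("vsl_base", "wage_base", "wage_target", "cpi_base", "cpi_target",
                     "exchange_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        return self


class DiscountConvention(str, Enum):
    GEOMETRIC_ANNUAL = "geometric_annual"
    FIXTURE = "fixture"


@dataclass(frozen=True)
class DiscountSpec:
    """How period-average VSLs are discounted from a base year.

    ``geometric_annual``: each calendar year y is discounted by
    (1+rate)^-(y-base_year) and years within a period are averaged.
    ``fixture``: a user-supplied schedule is used verbatim.
    """

    annual_rate: float = 0.02
    base_year: int = 2020
    convention: DiscountConvention = DiscountConvention.GEOMETRIC_ANNUAL

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_rate < 1.0:
            raise ValidationError(f"annual_rate must lie in [0, 1), got {self.annual_rate}")


@dataclass
class VSLSchedule:
    """VSL in USD/person keyed by (age_group, period)."""

    vsl: pd.Series

    def __post_init__(self) -> None:
        self.vsl = _require_index(self.vsl, ("age_group", "period"), "VSLSchedule")
        bad = self.vsl[self.vsl <= 0]
        if not bad.empty:
            raise ValidationError(
                f"VSLSchedule: non-positive VSL {bad.iloc[0]} at {tuple(bad.index[0])}",
                key=tuple(bad.index[0]),
            )

    def slice_period(self, period_id: str) -> pd.Series:
        if period_id not in self.vsl.index.get_level_values("period"):
            raise ValidationError(f"VSLSchedule: period {period_id!r} absent", key=period_id)
        return self.vsl.xs(period_id, level="period")


@dataclass
class MonetizedMortalityTable:
    """Expected cancer-death cost in USD by (age_group, region, period)."""

    mdc: pd.Series

    def __post_init__(self) -> None:
        self.mdc = _require_index(self.mdc, ("age_group", "region", "period"), "MonetizedMortalityTable")
        _check_nonnegative(self.mdc, "MonetizedMortalityTable.mdc")

    def slice_period(self, period_id: str) -> pd.Series:
        return self.mdc.xs(period_id, level="period")


def transfer_vsl_nominal(params: ValueTransferParams) -> float:
    """Wage-growth-adjusted nominal VSL in the target year (USD).

    Applies the earnings elasticity to the percent change in average
    monthly earnings between base and target year.
    """
    pct_wage_change = 100.0 * (params.wage_target - params.wage_base) / params.wage_base
    return params.vsl_base * 1e6 * (1.0 + params.earnings_elasticity * pct_wage_change / 100.0)


def deflate_vsl_real(params: ValueTransferParams, nominal: float) -> float:
    """Real (CPI-deflated) VSL in base-year prices (USD)."""
    if nominal <= 0:
        raise ValidationError(f"nominal VSL must be > 0, got {nominal}")
    return nominal * params.cpi_base / params.cpi_target


def build_vsl_schedule(
    base_vsl_by_group: Mapping[str, float],
    periods: Sequence[Period],
    spec: DiscountSpec,
    fixture: pd.Series | None = None,
) -> VSLSchedule:
    """Per-period VSL schedule for each age group.

    Under ``geometric_annual`` each group's base-year VSL is multiplied by
    the mean discount factor of the calendar years in the period:

        vsl[i,t] = base[i] * mean_{y in t} (1 + rate)^-(y - base_year)

    Under ``fixture`` the supplied (age_group, period)-indexed series is
    returned verbatim (used to reproduce a published schedule).
    """
    if spec.convention == DiscountConvention.FIXTURE:
        if fixture is None:
            raise ValidationError("convention 'fixture' requires a fixture schedule")
        return VSLSchedule(vsl=fixture)
    if spec.convention != DiscountConvention.GEOMETRIC_ANNUAL:  # pragma: no cover
        raise ValidationError(
            f"unknown discount convention {spec.convention!r}; supported: "
            f"{[c.value for c in DiscountConvention]}"
        )
    for group, base in base_vsl_by_group.items():
        if base <= 0:
            raise ValidationError(f"base VSL for {group!r} must be > 0, got {base}")
    rows = {}
    for period in periods:
        factors = [(1.0 + spec.annual_rate) ** -(y - spec.base_year) for y in period.years]
        mean_factor = sum(factors) / len(factors)
        for group, base in base_vsl_by_group.items():
            rows[(group, period.id)] = base * mean_factor
    vsl = pd.Series(rows)
    vsl.index = pd.MultiIndex.from_tuples(vsl.index, names=("age_group", "period"))
    return VSLSchedule(vsl=vsl)


def monetize_deaths(
    deaths: pd.Series, schedule: VSLSchedule, period: Period | str
) -> pd.Series:
    """Monetized expected cancer mortality for one period (USD).

    ``deaths`` is indexed by (age_group, region); the result keeps that
    index.  Every age group present in ``deaths`` must be covered by the
    schedule for the period.
    """
    period_id = period.id if isinstance(period, Period) else period
    vsl = schedule.slice_period(period_id)
    groups = deaths.index.get_level_values("age_group")
    missing = set(groups) - set(vsl.index)
    if missing:
        group = sorted(missing)[0]
        raise ValidationError(
            f"VSLSchedule: no VSL for ({group!r}, {period_id!r})", key=(group, period_id)
        )
    mdc = deaths * vsl.reindex(groups).to_numpy()
    mdc.name = "mdc"
    return mdc
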