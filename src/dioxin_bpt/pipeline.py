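"""Scenario container, validation, and the end-to-end pipeline run.

A :class:`Scenario` bundles everything one run consumes: the age-group /
region / period grid, the dose (or risk) table, risk coefficients,
population projections, a VSL schedule, and the policy/baseline emission
paths.  :func:`run_pipeline` chains dose -> risk -> expected deaths ->
monetized mortality -> per-gram benefits and returns the three result
tables plus a recomputable summary block.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import (
    AgeGroup,
    ExposureTable,
    Period,
    PopulationTable,
    Region,
    RiskCoefficients,
    compute_cancer_risk,
    expected_at_risk,
    expected_deaths,
)
from .engine import (
    BASELINE,
    POLICY,
    EmissionTrajectory,
    bpt_national,
    net_bpt_table,
)
from .errors import StageError, ValidationError
from .valuation import (
    DiscountSpec,
    MonetizedMortalityTable,
    ValueTransferParams,
    VSLSchedule,
    monetize_deaths,
)

__all__ = ["Finding", "Scenario", "RunReport", "validate_scenario", "run_pipeline"]

logger = logging.getLogger(__name__)

# Sub-region shares are long-run averages rounded independently, so their sum
# drifts from 1; drift beyond this band is worth a warning.
_SHARE_SUM_WARN_BAND = 0.01


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    severity: str
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.path}: {self.message}"


@dataclass
class Scenario:
    """The complete input bundle for one pipeline run."""

    age_groups: list[AgeGroup]
    regions: list[Region]
    periods: list[Period]
    exposure: ExposureTable
    coeffs: RiskCoefficients
    populations: PopulationTable
    vsl: VSLSchedule
    trajectory: EmissionTrajectory
    transfer_params: ValueTransferParams | None = None
    discount: DiscountSpec | None = None
    region_shares: dict[str, float] | None = None
    provenance: str = ""

    @property
    def base_period(self) -> Period:
        return self.periods[0]

    @property
    def national_region(self) -> Region:
        nationals = [r for r in self.regions if r.is_national]
        if len(nationals) != 1:
            raise ValidationError(
                f"scenario must designate exactly one national region, found {len(nationals)}"
            )
        return nationals[0]

    @property
    def grid(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [[g.value for g in self.age_groups], [r.id for r in self.regions]],
            names=("age_group", "region"),
        )

    def copy(self) -> "Scenario":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class RunReport:
    """Pipeline output: result tables plus a summary recomputable from them."""

    mdc: MonetizedMortalityTable
    emissions: EmissionTrajectory
    net_bpt: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _digest(obj) -> str:
    if isinstance(obj, pd.Series):
        payload = obj.to_csv()
    elif isinstance(obj, pd.DataFrame):
        payload = obj.to_csv()
    else:
        payload = repr(obj)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_scenario(scenario: Scenario) -> list[Finding]:
    """Check every cross-table invariant; returns findings, never raises.

    An empty list means the scenario is runnable.
    """
    findings: list[Finding] = []

    def err(path: str, message: str) -> None:
        findings.append(Finding("error", path, message))

    def warn(path: str, message: str) -> None:
        findings.append(Finding("warning", path, message))

    region_ids = [r.id for r in scenario.regions]
    if len(set(region_ids)) != len(region_ids):
        err("regions", "region ids are not unique")
    nationals = [r for r in scenario.regions if r.is_national]
    if len(nationals) != 1:
        err("regions", f"expected exactly one national region, found {len(nationals)}")

    period_ids = [p.id for p in scenario.periods]
    if len(set(period_ids)) != len(period_ids):
        err("periods", "period ids are not unique")
    for prev, nxt in zip(scenario.periods, scenario.periods[1:]):
        if nxt.start_year <= prev.end_year:
            err("periods", f"periods {prev.id!r} and {nxt.id!r} overlap or are unordered")

    grid = scenario.grid
    missing = grid.difference(scenario.exposure.grid)
    for key in missing:
        err("exposure", f"missing cell {tuple(key)}")

    full_grid = pd.MultiIndex.from_product(
        [[g.value for g in scenario.age_groups], region_ids, period_ids],
        names=("age_group", "region", "period"),
    )
    missing = full_grid.difference(scenario.populations.count.index)
    for key in list(missing)[:10]:
        err("populations", f"missing cell {tuple(key)}")

    vsl_grid = pd.MultiIndex.from_product(
        [[g.value for g in scenario.age_groups], period_ids],
        names=("age_group", "period"),
    )
    missing = vsl_grid.difference(scenario.vsl.vsl.index)
    for key in list(missing)[:10]:
        err("vsl", f"missing cell {tuple(key)}")

    traj_grid = pd.MultiIndex.from_product(
        [region_ids, period_ids], names=("region", "period")
    )
    emissions = scenario.trajectory.emissions
    missing = traj_grid.difference(emissions.index)
    for key in list(missing)[:10]:
        err("trajectory", f"missing cell {tuple(key)}")
    present = emissions.loc[emissions.index.intersection(traj_grid)]
    over = present[present[POLICY] > present[BASELINE] * (1 + 1e-12)]
    for key in over.index:
        err("trajectory", f"policy emissions exceed baseline at {tuple(key)}")

    if scenario.region_shares is not None:
        for region_id, share in scenario.region_shares.items():
            if share < 0:
                err("region_shares", f"negative share for {region_id!r}")
        total = sum(scenario.region_shares.values())
        if total > 1 + 1e-6:
            err("region_shares", f"shares sum to {total:.4f} > 1")
        elif abs(total - 1.0) > _SHARE_SUM_WARN_BAND:
            warn("region_shares", f"shares sum to {total:.4f}, not 1")

    return findings


def compute_monetized_mortality(
    scenario: Scenario, deaths_decimals: int | None = None
) -> MonetizedMortalityTable:
    """Dose -> risk -> expected deaths -> USD, over the full period grid.

    By default expected deaths stay fractional with full precision (the
    chain is continuous).  ``deaths_decimals`` quantizes expected deaths to
    that many decimal places (persons) before monetization; the published
    Taiwan tables were produced with ``deaths_decimals=4``, which is why
    their small-count cells differ visibly from the continuous chain.
    """
    risk = compute_cancer_risk(scenario.exposure, scenario.coeffs)
    pieces = []
    for period in scenario.periods:
        er = expected_at_risk(risk, scenario.populations, period)
        deaths = expected_deaths(er, scenario.coeffs)
        if deaths_decimals is not None:
            deaths = deaths.round(deaths_decimals)
        mdc = monetize_deaths(deaths, scenario.vsl, period)
        mdc = pd.concat({period.id: mdc}, names=["period"])
        pieces.append(mdc)
    combined = pd.concat(pieces).reorder_levels(["age_group", "region", "period"])
    return MonetizedMortalityTable(mdc=combined)


def run_pipeline(
    scenario: Scenario, mdc: MonetizedMortalityTable | None = None
) -> RunReport:
    """Run the full chain and summarise.

    ``mdc`` lets callers inject a precomputed monetized-mortality table
    (e.g. a published one) and run only the benefit-per-gram stage on it;
    by default the table is computed from the scenario's own dose chain.
    The run is deterministic: identical inputs give identical reports.
    """
    findings = validate_scenario(scenario)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValidationError(
            "scenario failed validation: " + "; ".join(str(f) for f in errors[:5])
        )

    if mdc is None:
        try:
            mdc = compute_monetized_mortality(scenario)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise StageError("monetized_mortality", exc) from exc
    logger.info("mdc table digest %s", _digest(mdc.mdc))

    try:
        result = net_bpt_table(mdc, scenario.trajectory)
    except Exception as exc:  # noqa: BLE001
        raise StageError("bpt", exc) from exc
    logger.info("net BPT table digest %s", _digest(result))

    national = scenario.national_region.id
    base = scenario.base_period.id
    later_periods = [p.id for p in scenario.periods[1:]]
    regional = result[result["level"] == "region"].set_index(["region", "period"])

    def _cumulative(region_id: str) -> float:
        if not later_periods:
            return 0.0
        return float(regional.loc[(region_id, later_periods), "net"].sum())

    summary = {
        "headline_bpt_usd_per_gram": bpt_national(
            mdc, scenario.trajectory, POLICY, national, base
        ),
        "base_period": base,
        "national_region": national,
        "cumulative_net_bpt": {
            r.id: _cumulative(r.id) for r in scenario.regions
        },
        "net_bpt_by_period_national": {
            pid: float(regional.loc[(national, pid), "net"]) for pid in [base] + later_periods
        },
    }
    return RunReport(mdc=mdc, emissions=scenario.trajectory, net_bpt=result, summary=summary)
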