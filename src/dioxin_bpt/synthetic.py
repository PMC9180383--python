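"""Random scenario generation with the structure the analysis assumes.

Generated scenarios mirror the study grid: K sub-regions plus a first-class
national aggregate, three age groups, a single base year followed by 5-year
projection periods.  Doses are log-uniform (regional doses span orders of
magnitude), populations decline geometrically (the projected national
population falls roughly 25% over fifty years), VSL schedules are
geometrically discounted, and the policy emission path declines linearly to
a configurable fraction of the base level.  Identical seeds give identical
scenarios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import AgeGroup, ExposureTable, Period, PopulationTable, Region, RiskCoefficients
from .engine import TrajectorySegment, build_trajectory
from .errors import ValidationError
from .pipeline import Scenario
from .valuation import DiscountConvention, DiscountSpec, build_vsl_schedule

__all__ = ["SynthConfig", "generate_scenario", "allocate_population"]


class SynthConfig(BaseModel):
    """Knobs for the generator; defaults emulate the study's magnitudes."""

    n_regions: int = Field(default=4, ge=1)          # sub-regions (aggregate is extra)
    n_periods: int = Field(default=11, ge=2)         # base year + projection periods
    seed: int = 0
    ladd_range: tuple[float, float] = (8e-5, 3e-2)   # pg-TEQ/kg/day, spans the study doses
    pop_range: tuple[float, float] = (5e5, 2e7)      # national persons per age group
    vsl_range: tuple[float, float] = (2e6, 2.6e7)    # USD/person
    base_emission_range: tuple[float, float] = (0.5, 32.0)  # grams/region/year
    reduction_fraction: float = Field(default=0.5, gt=0.0, le=1.0)  # policy endpoint
    drift: float = Field(default=0.028, ge=0.0, lt=1.0)  # per-period population decline
    csf: float = 1.0e-4
    mortality_risk: float = 0.2278
    discount_rate: float = 0.02

    @model_validator(mode="after")
    def _ranges(self) -> "SynthConfig":
        for name in ("ladd_range", "pop_range", "vsl_range", "base_emission_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an ordered positive interval, got ({lo}, {hi})")
        return self


def allocate_population(
    national: pd.Series,
    shares: dict[str, float],
    national_region_id: str = "national",
) -> PopulationTable:
    """Spread national counts over sub-regions by fixed population shares.

    ``national`` is indexed by (age_group, period).  Shares are applied
    uniformly across age groups; the aggregate region keeps the full
    national count.  Shares must be nonnegative and sum to at most 1 (they
    may fall short: long-run average shares need not add up exactly).
    """
    for region_id, share in shares.items():
        if share < 0:
            raise ValidationError(f"negative share for region {region_id!r}", key=region_id)
    total = sum(shares.values())
    if total > 1 + 1e-9:
        raise ValidationError(f"shares sum to {total}, exceeding 1")
    national = national.copy()
    national.index = national.index.set_names(["age_group", "period"])
    pieces = {region_id: national * share for region_id, share in shares.items()}
    pieces[national_region_id] = national
    combined = pd.concat(pieces, names=["region"])
    count = combined.reorder_levels(["age_group", "region", "period"])
    count.name = "count"
    return PopulationTable(count=count)


def generate_scenario(config: SynthConfig) -> Scenario:
    """Draw a complete, validating scenario from the given configuration."""
    rng = np.random.default_rng(config.seed)
    groups = [g.value for g in AgeGroup]
    sub_ids = [f"region_{k + 1}" for k in range(config.n_regions)]
    national_id = "national"
    regions = [Region(rid, rid.replace("_", " ")) for rid in sub_ids]
    regions.append(Region(national_id, "aggregate", is_national=True))

    base_year = 2020
    periods = [Period(str(base_year), base_year, base_year)]
    for k in range(config.n_periods - 1):
        start = base_year + 1 + 5 * k
        periods.append(Period(f"{start}-{start + 4}", start, start + 4))

    # doses: log-uniform per (age_group, region), aggregate drawn first-class
    lo, hi = config.ladd_range
    all_ids = sub_ids + [national_id]
    ladd = pd.Series(
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(groups) * len(all_ids))),
        index=pd.MultiIndex.from_product([groups, all_ids], names=("age_group", "region")),
        name="ladd",
    )

    # national population per age group, declining by ``drift`` per period
    lo, hi = config.pop_range
    base_pop = rng.uniform(lo, hi, size=len(groups))
    decline = (1.0 - config.drift) ** np.arange(config.n_periods)
    national_pop = pd.Series(
        {
            (g, p.id): base_pop[gi] * decline[ti]
            for gi, g in enumerate(groups)
            for ti, p in enumerate(periods)
        }
    )
    national_pop.index = national_pop.index.set_names(["age_group", "period"])
    shares = dict(zip(sub_ids, map(float, rng.dirichlet(np.ones(config.n_regions)))))
    populations = allocate_population(national_pop, shares, national_region_id=national_id)

    # VSL: one base value per group (older adults valued highest, as in
    # hedonic-wage estimates dominated by retirement-age risk premia)
    lo, hi = config.vsl_range
    vsl_base = dict(zip(groups, np.sort(rng.uniform(lo, hi, size=len(groups)))))
    discount = DiscountSpec(
        annual_rate=config.discount_rate,
        base_year=base_year,
        convention=DiscountConvention.GEOMETRIC_ANNUAL,
    )
    vsl = build_vsl_schedule(vsl_base, periods, discount)

    # emissions: regional bases, national = regional total, linear reduction
    lo, hi = config.base_emission_range
    base_emissions = dict(zip(sub_ids, rng.uniform(lo, hi, size=config.n_regions)))
    base_emissions[national_id] = sum(base_emissions.values())
    segment = TrajectorySegment(
        start_period_index=0,
        end_period_index=config.n_periods - 1,
        start_level=1.0,
        end_level=config.reduction_fraction,
    )
    trajectory = build_trajectory(base_emissions, [segment], periods)

    return Scenario(
        age_groups=list(AgeGroup),
        regions=regions,
        periods=periods,
        exposure=ExposureTable(ladd=ladd),
        coeffs=RiskCoefficients(csf=config.csf, mortality_risk=config.mortality_risk),
        populations=populations,
        vsl=vsl,
        transfer_params=None,
        discount=discount,
        trajectory=trajectory,
        region_shares=shares,
        provenance=f"synthetic scenario (seed={config.seed})",
    )
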