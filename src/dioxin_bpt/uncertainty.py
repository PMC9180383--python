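"""One-at-a-time perturbation sweeps of the pipeline's key parameters.

Each sweep perturbs exactly one parameter (multiplicatively, or by swapping
in a replacement population table), re-runs the whole pipeline, and reports
the percent change of a chosen benefit-per-gram value.  Because the chain
is linear in every factor, a uniform multiplicative perturbation of the VSL
(or dose, slope factor, mortality risk) moves every BPT by exactly the same
factor; population perturbations scoped to one age group move the result by
that group's share of the monetized burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import pandas as pd

from .core import PopulationTable
from .engine import POLICY
from .errors import ValidationError
from .pipeline import RunReport, Scenario, run_pipeline

__all__ = ["SweepParameter", "SweepSpec", "SweepResult", "run_sweep", "tornado_summary"]


class SweepParameter(str, Enum):
    VSL = "vsl"
    POPULATION = "population"
    CSF = "csf"
    MORTALITY_RISK = "mortality_risk"
    LADD = "ladd"


@dataclass(frozen=True)
class SweepSpec:
    """What to perturb and by how much.

    ``age_group`` / ``period`` optionally restrict the perturbation's scope
    (where the parameter carries that dimension).  ``replacement`` swaps in
    an absolute population table instead of scaling (population only), e.g.
    a high- or low-variant projection.
    """

    parameter: SweepParameter
    multipliers: tuple[float, ...] = ()
    age_group: str | None = None
    period: str | None = None
    replacement: PopulationTable | None = None

    def __post_init__(self) -> None:
        try:
            SweepParameter(self.parameter)
        except ValueError:
            raise ValidationError(
                f"unknown parameter {self.parameter!r}; valid names: "
                f"{[p.value for p in SweepParameter]}"
            ) from None
        if any(m <= 0 for m in self.multipliers):
            raise ValidationError("multipliers must be positive")
        if self.replacement is None and not self.multipliers:
            raise ValidationError("a sweep needs multipliers or a replacement table")

    @property
    def label(self) -> str:
        scope = [s for s in (self.age_group, self.period) if s]
        param = SweepParameter(self.parameter).value
        return param + (f"[{','.join(scope)}]" if scope else "")


@dataclass
class SweepResult:
    """Baseline and perturbed BPT values with signed percent changes."""

    label: str
    baseline_bpt: float
    multipliers: tuple[float, ...]
    perturbed_bpt: list[float] = field(default_factory=list)

    @property
    def pct_change(self) -> list[float]:
        return [100.0 * (v - self.baseline_bpt) / self.baseline_bpt for v in self.perturbed_bpt]

    @property
    def max_abs_pct_change(self) -> float:
        return max((abs(p) for p in self.pct_change), default=0.0)


def _scoped_mask(index: pd.MultiIndex, spec: SweepSpec) -> pd.Series:
    mask = pd.Series(True, index=index)
    if spec.age_group is not None and "age_group" in index.names:
        mask &= index.get_level_values("age_group") == spec.age_group
        if not mask.any():
            raise ValidationError(f"age_group {spec.age_group!r} not in scenario")
    if spec.period is not None and "period" in index.names:
        mask &= index.get_level_values("period") == spec.period
    return mask


def _perturb(scenario: Scenario, spec: SweepSpec, multiplier: float) -> Scenario:
    """A deep copy of the scenario with exactly one parameter changed."""
    out = scenario.copy()
    param = SweepParameter(spec.parameter)
    if param is SweepParameter.VSL:
        mask = _scoped_mask(out.vsl.vsl.index, spec)
        out.vsl.vsl = out.vsl.vsl.where(~mask, out.vsl.vsl * multiplier)
    elif param is SweepParameter.POPULATION:
        if spec.replacement is not None:
            out.populations = spec.replacement
        else:
            mask = _scoped_mask(out.populations.count.index, spec)
            out.populations.count = out.populations.count.where(
                ~mask, out.populations.count * multiplier
            )
    elif param is SweepParameter.CSF:
        out.coeffs = replace(out.coeffs, csf=out.coeffs.csf * multiplier)
    elif param is SweepParameter.MORTALITY_RISK:
        out.coeffs = replace(out.coeffs, mortality_risk=out.coeffs.mortality_risk * multiplier)
    elif param is SweepParameter.LADD:
        mask = _scoped_mask(out.exposure.ladd.index, spec)
        out.exposure.ladd = out.exposure.ladd.where(~mask, out.exposure.ladd * multiplier)
    return out


def _extract_bpt(
    report: RunReport,
    scenario: Scenario,
    level: str,
    region: str | None,
    age_group: str | None,
    period_id: str | None,
    path: str,
) -> float:
    if level == "national":
        region = scenario.national_region.id
        lookup_level = "region"
    elif level == "region":
        lookup_level = "region"
    elif level == "group":
        lookup_level = "group"
    else:
        raise ValidationError(f"unknown level {level!r}; expected national, region or group")
    if region is None:
        raise ValidationError("a region is required at this level")
    period_id = period_id or scenario.base_period.id
    sel = report.net_bpt
    sel = sel[(sel["level"] == lookup_level) & (sel["region"] == region)
              & (sel["period"] == period_id)]
    if lookup_level == "group":
        sel = sel[sel["age_group"] == age_group]
    if sel.empty:
        raise ValidationError(
            f"no BPT value at level={level!r} region={region!r} period={period_id!r}"
        )
    return float(sel[path].iloc[0])


def run_sweep(
    scenario: Scenario,
    spec: SweepSpec,
    level: str = "national",
    region: str | None = None,
    age_group: str | None = None,
    period_id: str | None = None,
    path: str = POLICY,
) -> SweepResult:
    """Re-run the pipeline once per multiplier and report percent changes.

    The tracked quantity defaults to the national per-gram benefit in the
    base period on the policy path.  The input scenario is never mutated.
    """
    baseline_report = run_pipeline(scenario)
    baseline = _extract_bpt(baseline_report, scenario, level, region, age_group, period_id, path)
    if baseline <= 0:
        raise ValidationError(f"baseline BPT must be > 0 to report percent change, got {baseline}")

    multipliers = spec.multipliers if spec.multipliers else (1.0,)
    result = SweepResult(label=spec.label, baseline_bpt=baseline, multipliers=multipliers)
    for multiplier in multipliers:
        perturbed = _perturb(scenario, spec, multiplier)
        report = run_pipeline(perturbed)
        result.perturbed_bpt.append(
            _extract_bpt(report, perturbed, level, region, age_group, period_id, path)
        )
    return result


def tornado_summary(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Parameters ranked by largest absolute percent change (descending).

    Ties are broken alphabetically by label.
    """
    if not results:
        raise ValidationError("tornado_summary requires at least one sweep result")
    df = pd.DataFrame(
        {
            "parameter": [r.label for r in results],
            "max_abs_pct_change": [r.max_abs_pct_change for r in results],
        }
    )
    df = df.sort_values(
        ["max_abs_pct_change", "parameter"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)
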