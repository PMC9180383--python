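"""Benefit-per-gram (BPT) engine: emission trajectories and per-gram benefits.

The benefit per ton (here, per gram TEQ) divides the monetized cancer burden
by the emission mass it is attributed to, under the uniform-mixing
assumption:

    group level:    BPT[i,j,t] = mdc[i,j,t] / E[j,t]
    region level:   BPT[j,t]   = sum_i mdc[i,j,t] / E[j,t]
    national:       BPT[t]     = sum_i mdc[i,nat,t] / E[nat,t]

A policy path (declining emissions) and a baseline path (no action) give a
net per-gram benefit of the reduction plan,

    net[.,t] = mdc * (1/E_policy - 1/E_baseline),

which is zero whenever the paths coincide and positive whenever the policy
path is below baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Period
from .errors import ValidationError
from .valuation import MonetizedMortalityTable

__all__ = [
    "POLICY",
    "BASELINE",
    "EmissionTrajectory",
    "TrajectorySegment",
    "build_trajectory",
    "bpt_group",
    "bpt_region",
    "bpt_national",
    "net_bpt",
    "net_bpt_table",
    "cumulative_net_bpt",
    "share_of_total",
]

POLICY = "policy"
BASELINE = "baseline"


@dataclass
class EmissionTrajectory:
    """Grams TEQ by (region, period) for the policy and baseline paths."""

    emissions: pd.DataFrame  # index (region, period); columns policy, baseline

    def __post_init__(self) -> None:
        df = self.emissions
        if not isinstance(df, pd.DataFrame) or set(df.columns) != {POLICY, BASELINE}:
            raise ValidationError(
                "EmissionTrajectory: expected a DataFrame with columns "
                f"{{{POLICY!r}, {BASELINE!r}}}"
            )
        df = df.astype(float).copy()
        df.index = df.index.set_names(["region", "period"])
        bad = df[(df[POLICY] <= 0) | (df[BASELINE] <= 0)]
        if not bad.empty:
            raise ValidationError(
                f"EmissionTrajectory: non-positive emissions at {tuple(bad.index[0])}",
                key=tuple(bad.index[0]),
            )
        over = df[df[POLICY] > df[BASELINE] * (1 + 1e-12)]
        if not over.empty:
            raise ValidationError(
                f"EmissionTrajectory: policy exceeds baseline at {tuple(over.index[0])}",
                key=tuple(over.index[0]),
            )
        self.emissions = df

    def level(self, path: str, region: str, period_id: str) -> float:
        if path not in (POLICY, BASELINE):
            raise ValidationError(f"unknown path {path!r}; expected {POLICY!r} or {BASELINE!r}")
        try:
            return float(self.emissions.loc[(region, period_id), path])
        except KeyError:
            raise ValidationError(
                f"EmissionTrajectory: no emissions for ({region!r}, {period_id!r})",
                key=(region, period_id),
            ) from None


@dataclass(frozen=True)
class TrajectorySegment:
    """A linear-reduction leg of a policy path, in period-index coordinates.

    Levels are either grams or fractions of the base level; ``end_level`` may
    not exceed ``start_level`` (reduction plans only).
    """

    start_period_index: int
    end_period_index: int
    start_level: float
    end_level: float

    def __post_init__(self) -> None:
        if self.end_period_index <= self.start_period_index:
            raise ValidationError(
                f"segment indices must increase, got {self.start_period_index} -> "
                f"{self.end_period_index}"
            )
        if self.start_level <= 0 or self.end_level <= 0:
            raise ValidationError("segment levels must be > 0")
        if self.end_level > self.start_level:
            raise ValidationError(
                f"segment must not increase emissions ({self.start_level} -> {self.end_level})"
            )


def build_trajectory(
    base: Mapping[str, float],
    segments: Sequence[TrajectorySegment],
    periods: Sequence[Period],
) -> EmissionTrajectory:
    """Piecewise-linear policy path over the period axis, flat baseline.

    ``base`` maps region id to its base-period emissions (grams).  Segments
    are expressed as fractions of the base level (start of the first segment
    must be 1.0, i.e. the base level at period index 0) and must tile the
    period axis without gaps or overlaps.  Within a segment the fraction
    falls in equal per-period steps; every region is scaled proportionally
    from its own base.  The baseline path holds the base level in every
    period.
    """
    if not segments:
        raise ValidationError("at least one segment is required")
    segs = sorted(segments, key=lambda s: s.start_period_index)
    if segs[0].start_period_index != 0:
        raise ValidationError("first segment must start at period index 0 (the base level)")
    if abs(segs[0].start_level - 1.0) > 1e-12:
        raise ValidationError(
            f"first segment must start at the base level (fraction 1.0), got {segs[0].start_level}"
        )
    for prev, nxt in zip(segs, segs[1:]):
        if nxt.start_period_index != prev.end_period_index:
            raise ValidationError(
                f"segments must tile the period axis: gap/overlap between period index "
                f"{prev.end_period_index} and {nxt.start_period_index}"
            )
        if abs(nxt.start_level - prev.end_level) > 1e-12:
            raise ValidationError(
                f"segment levels must be continuous: {prev.end_level} != {nxt.start_level}"
            )
    if segs[-1].end_period_index != len(periods) - 1:
        raise ValidationError(
            f"segments must end at the last period index {len(periods) - 1}, "
            f"got {segs[-1].end_period_index}"
        )

    fractions = np.empty(len(periods))
    fractions[0] = 1.0
    for seg in segs:
        n_steps = seg.end_period_index - seg.start_period_index
        step = (seg.start_level - seg.end_level) / n_steps
        for k in range(1, n_steps + 1):
            fractions[seg.start_period_index + k] = seg.start_level - step * k

    rows = []
    for region, level in base.items():
        for frac, period in zip(fractions, periods):
            rows.append((region, period.id, level * frac, level))
    df = pd.DataFrame(rows, columns=["region", "period", POLICY, BASELINE])
    df = df.set_index(["region", "period"])
    return EmissionTrajectory(emissions=df)


def _guard_emissions(e: float, region: str, period_id: str) -> None:
    if e <= 0:
        raise ValidationError(
            f"emissions must be > 0 to form a per-gram value at ({region!r}, {period_id!r})",
            key=(region, period_id),
        )


def bpt_group(
    mdc: MonetizedMortalityTable,
    traj: EmissionTrajectory,
    path: str,
    age_group: str,
    region: str,
    period_id: str,
) -> float:
    """Per-gram benefit for one age group: mdc[i,j,t] / E[j,t] (USD/gram)."""
    e = traj.level(path, region, period_id)
    _guard_emissions(e, region, period_id)
    return float(mdc.mdc.loc[(age_group, region, period_id)]) / e


def bpt_region(
    mdc: MonetizedMortalityTable,
    traj: EmissionTrajectory,
    path: str,
    region: str,
    period_id: str,
) -> float:
    """Per-gram benefit for a region: summed mdc over age groups / E[j,t]."""
    e = traj.level(path, region, period_id)
    _guard_emissions(e, region, period_id)
    total = float(mdc.slice_period(period_id).xs(region, level="region").sum())
    return total / e


def bpt_national(
    mdc: MonetizedMortalityTable,
    traj: EmissionTrajectory,
    path: str,
    national_region: str,
    period_id: str,
) -> float:
    """National per-gram benefit: the designated aggregate region's summed
    mdc over the nation-total emissions."""
    return bpt_region(mdc, traj, path, national_region, period_id)


def net_bpt(
    mdc: MonetizedMortalityTable,
    traj: EmissionTrajectory,
    region: str,
    period_id: str,
    age_group: str | None = None,
) -> float:
    """Net per-gram benefit of the reduction plan (USD/gram).

    Computes ``mdc_agg * (1/E_policy - 1/E_baseline)`` where ``mdc_agg`` is
    the single-group value when ``age_group`` is given, else the regional
    sum over age groups.  Zero when the two paths coincide.
    """
    e_policy = traj.level(POLICY, region, period_id)
    e_base = traj.level(BASELINE, region, period_id)
    _guard_emissions(e_policy, region, period_id)
    _guard_emissions(e_base, region, period_id)
    if age_group is None:
        agg = float(mdc.slice_period(period_id).xs(region, level="region").sum())
    else:
        agg = float(mdc.mdc.loc[(age_group, region, period_id)])
    return agg * (1.0 / e_policy - 1.0 / e_base)


def net_bpt_table(mdc: MonetizedMortalityTable, traj: EmissionTrajectory) -> pd.DataFrame:
    """Long-format BPT result over the full (region, period) grid.

    One row per (level, age_group, region, period) with columns
    ``policy``, ``baseline`` and ``net`` in USD/gram.  ``level`` is
    ``group`` for per-age-group rows and ``region`` for summed rows (the
    aggregate region's summed row is the national value).
    """
    rows = []
    for (region, period_id), e in traj.emissions.iterrows():
        try:
            sliced = mdc.slice_period(period_id).xs(region, level="region")
        except KeyError:
            continue
        inv_gap = 1.0 / e[POLICY] - 1.0 / e[BASELINE]
        for age_group, value in sliced.items():
            rows.append(
                ("group", age_group, region, period_id,
                 value / e[POLICY], value / e[BASELINE], value * inv_gap)
            )
        total = float(sliced.sum())
        rows.append(
            ("region", None, region, period_id,
             total / e[POLICY], total / e[BASELINE], total * inv_gap)
        )
    return pd.DataFrame(
        rows,
        columns=["level", "age_group", "region", "period", POLICY, BASELINE, "net"],
    )


def cumulative_net_bpt(
    result: pd.DataFrame,
    period_ids: Iterable[str],
    region: str,
    age_group: str | None = None,
) -> float:
    """Sum of net per-gram benefits over the listed periods (USD/gram)."""
    period_ids = list(period_ids)
    if not period_ids:
        return 0.0
    level = "group" if age_group is not None else "region"
    sel = result[(result["level"] == level) & (result["region"] == region)]
    if age_group is not None:
        sel = sel[sel["age_group"] == age_group]
    available = set(sel["period"])
    for pid in period_ids:
        if pid not in available:
            raise ValidationError(f"period {pid!r} absent from BPT result", key=pid)
    sel = sel[sel["period"].isin(period_ids)]
    return float(sel["net"].sum())


def share_of_total(part: float, whole_parts: Sequence[float]) -> float:
    """Fraction of ``part`` in the sum of ``whole_parts``."""
    total = float(sum(whole_parts))
    if total <= 0:
        raise ValidationError(f"sum of whole_parts must be > 0, got {total}")
    return part / total
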