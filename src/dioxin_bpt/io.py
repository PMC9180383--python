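"""Reading and writing scenario bundles and run reports.

A scenario bundle is a directory of long-format UTF-8 CSVs plus a
``scenario.yaml`` manifest naming them and holding the scalar blocks
(coefficients, value-transfer parameters, discounting, shares).  All CSVs
use a header row and dot decimal separators; floats round-trip exactly
(shortest-repr formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    AgeGroup,
    ExposureTable,
    Period,
    PopulationTable,
    Region,
    RiskCoefficients,
)
from .engine import BASELINE, POLICY, EmissionTrajectory
from .errors import ValidationError
from .pipeline import RunReport, Scenario
from .valuation import DiscountConvention, DiscountSpec, ValueTransferParams, VSLSchedule

__all__ = ["write_scenario", "read_scenario", "write_report"]

MANIFEST = "scenario.yaml"
_FILES = {
    "exposure": "exposure.csv",
    "population": "population.csv",
    "vsl": "vsl.csv",
    "trajectory": "trajectory.csv",
}


def _series_to_csv(series: pd.Series, path: Path, value_name: str) -> None:
    df = series.rename(value_name).reset_index()
    df.to_csv(path, index=False, float_format="%.17g")


def write_scenario(scenario: Scenario, out_dir: str | Path) -> Path:
    """Write the bundle; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _series_to_csv(scenario.exposure.ladd, out / _FILES["exposure"], "value")
    _series_to_csv(scenario.populations.count, out / _FILES["population"], "value")
    _series_to_csv(scenario.vsl.vsl, out / _FILES["vsl"], "vsl_usd")
    traj = scenario.trajectory.emissions.stack().rename("grams").reset_index()
    traj.columns = ["region", "period", "path", "grams"]
    traj.to_csv(out / _FILES["trajectory"], index=False, float_format="%.17g")

    manifest = {
        "provenance": scenario.provenance,
        "age_groups": [g.value for g in scenario.age_groups],
        "regions": [
            {"id": r.id, "label": r.label, "is_national": r.is_national}
            for r in scenario.regions
        ],
        "periods": [
            {"id": p.id, "start_year": p.start_year, "end_year": p.end_year}
            for p in scenario.periods
        ],
        "coefficients": {
            "csf": scenario.coeffs.csf,
            "mortality_risk": scenario.coeffs.mortality_risk,
        },
        "transfer_params": (
            scenario.transfer_params.model_dump() if scenario.transfer_params else None
        ),
        "discount": (
            {
                "annual_rate": scenario.discount.annual_rate,
                "base_year": scenario.discount.base_year,
                "convention": scenario.discount.convention.value,
            }
            if scenario.discount
            else None
        ),
        "region_shares": (
            {k: float(v) for k, v in scenario.region_shares.items()}
            if scenario.region_shares
            else None
        ),
        "files": dict(_FILES),
    }
    manifest_path = out / MANIFEST
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def _read_series(path: Path, index_cols: list[str], value_col: str) -> pd.Series:
    if not path.exists():
        raise ValidationError(f"bundle file {path.name!r} not found in {path.parent}")
    df = pd.read_csv(path, float_precision="round_trip")
    return df.set_index(index_cols)[value_col]


def read_scenario(manifest_path: str | Path) -> Scenario:
    """Load a bundle from its manifest (or the directory holding it)."""
    path = Path(manifest_path)
    if path.is_dir():
        path = path / MANIFEST
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    manifest = yaml.safe_load(path.read_text())
    base = path.parent
    files = manifest.get("files", _FILES)

    exposure = ExposureTable(
        ladd=_read_series(base / files["exposure"], ["age_group", "region"], "value")
    )
    populations = PopulationTable(
        count=_read_series(
            base / files["population"], ["age_group", "region", "period"], "value"
        )
    )
    vsl = VSLSchedule(
        vsl=_read_series(base / files["vsl"], ["age_group", "period"], "vsl_usd")
    )
    traj_df = pd.read_csv(base / files["trajectory"], float_precision="round_trip")
    wide = traj_df.pivot_table(
        index=["region", "period"], columns="path", values="grams", sort=False
    )[[POLICY, BASELINE]]
    trajectory = EmissionTrajectory(emissions=wide)

    coeffs = RiskCoefficients(**manifest["coefficients"])
    transfer = manifest.get("transfer_params")
    discount = manifest.get("discount")
    return Scenario(
        age_groups=[AgeGroup(g) for g in manifest["age_groups"]],
        regions=[Region(**r) for r in manifest["regions"]],
        periods=[Period(**p) for p in manifest["periods"]],
        exposure=exposure,
        coeffs=coeffs,
        populations=populations,
        vsl=vsl,
        trajectory=trajectory,
        transfer_params=ValueTransferParams(**transfer) if transfer else None,
        discount=(
            DiscountSpec(
                annual_rate=discount["annual_rate"],
                base_year=discount["base_year"],
                convention=DiscountConvention(discount["convention"]),
            )
            if discount
            else None
        ),
        region_shares=manifest.get("region_shares"),
        provenance=manifest.get("provenance", ""),
    )


def write_report(report: RunReport, out_dir: str | Path) -> Path:
    """Write result tables and the JSON summary; returns the summary path.

    ``mdc.csv``: age_group,region,period,usd.
    ``emissions.csv``: region,period,path,grams.
    ``net_bpt.csv``: level,age_group,region,period,path,usd_per_gram.
    ``summary.json``: headline and cumulative values recomputable from the
    tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _series_to_csv(report.mdc.mdc, out / "mdc.csv", "usd")
    traj = report.emissions.emissions.stack().rename("grams").reset_index()
    traj.columns = ["region", "period", "path", "grams"]
    traj.to_csv(out / "emissions.csv", index=False, float_format="%.17g")

    long = report.net_bpt.melt(
        id_vars=["level", "age_group", "region", "period"],
        value_vars=[POLICY, BASELINE, "net"],
        var_name="path",
        value_name="usd_per_gram",
    )
    long.to_csv(out / "net_bpt.csv", index=False, float_format="%.17g")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report.summary, indent=2, sort_keys=True))
    return summary_path
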