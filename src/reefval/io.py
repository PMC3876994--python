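"""CSV/JSON/YAML readers and writers for the pipeline's file interfaces.

Formats:

* cell table — CSV: cell_id, region, initial_cover_pct, hardground_weight
* climatology — CSV: cell_id, month (1–12), mean_c, sd_c
* scenario — JSON/YAML: name, co2_anchors, warming_anchors, climate_sensitivity
* parameters — YAML/JSON: growth block + per-region threshold/factor vectors
* SST series — CSV: cell_id, year, month, sst_c
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .scenarios import (
    ConfigurationError,
    EmissionsScenario,
    MonthlyClimatology,
    MonthlySSTSeries,
    YEARS,
)
from .simulator import BleachingParams, GrowthParams, ReefCell


def write_climatology_csv(
    climatologies: dict[str, MonthlyClimatology], path
) -> None:
    rows = [
        (cid, m, round(float(clim.monthly_mean[m - 1]), 6),
         round(float(clim.monthly_sd[m - 1]), 6))
        for cid, clim in sorted(climatologies.items())
        for m in range(1, 13)
    ]
    pd.DataFrame(rows, columns=["cell_id", "month", "mean_c", "sd_c"]).to_csv(
        path, index=False
    )


def read_climatology_csv(path) -> dict[str, MonthlyClimatology]:
    df = pd.read_csv(path)
    expected = {"cell_id", "month", "mean_c", "sd_c"}
    if not expected.issubset(df.columns):
        raise ConfigurationError(
            f"climatology CSV must have columns {sorted(expected)}"
        )
    out: dict[str, MonthlyClimatology] = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ConfigurationError(f"cell {cid}: needs months 1-12 exactly")
        out[str(cid)] = MonthlyClimatology(
            monthly_mean=grp["mean_c"].to_numpy(),
            monthly_sd=grp["sd_c"].to_numpy(),
        )
    return out


def write_cells_csv(cells: list[ReefCell], path) -> None:
    rows = [
        (c.cell_id, c.region, round(c.initial_cover, 6),
         round(c.hardground_weight, 6))
        for c in cells
    ]
    pd.DataFrame(
        rows, columns=["cell_id", "region", "initial_cover_pct", "hardground_weight"]
    ).to_csv(path, index=False)


def read_cells_csv(
    path, climatologies: dict[str, MonthlyClimatology]
) -> list[ReefCell]:
    df = pd.read_csv(path)
    expected = {"cell_id", "region", "initial_cover_pct", "hardground_weight"}
    if not expected.issubset(df.columns):
        raise ConfigurationError(f"cell CSV must have columns {sorted(expected)}")
    cells = []
    for row in df.itertuples(index=False):
        cid = str(row.cell_id)
        if cid not in climatologies:
            raise ConfigurationError(f"no climatology for cell {cid}")
        cells.append(
            ReefCell(
                cell_id=cid,
                region=str(row.region),
                initial_cover=float(row.initial_cover_pct),
                hardground_weight=float(row.hardground_weight),
                climatology=climatologies[cid],
            )
        )
    return cells


def write_scenario(scenario: EmissionsScenario, path) -> None:
    payload = {
        "name": scenario.name,
        "co2_anchors": [[y, v] for y, v in scenario.co2_anchors],
        "warming_anchors": [[y, v] for y, v in scenario.warming_anchors],
        "climate_sensitivity": scenario.climate_sensitivity,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_scenario(path) -> EmissionsScenario:
    path = Path(path)
    text = path.read_text()
    payload = (
        yaml.safe_load(text)
        if path.suffix in (".yml", ".yaml")
        else json.loads(text)
    )
    try:
        return EmissionsScenario(
            name=payload["name"],
            co2_anchors=[tuple(a) for a in payload["co2_anchors"]],
            warming_anchors=[tuple(a) for a in payload["warming_anchors"]],
            climate_sensitivity=float(payload.get("climate_sensitivity", 3.0)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"scenario file {path}: missing key {exc}") from exc


def read_parameters(path) -> tuple[GrowthParams, dict[str, BleachingParams]]:
    """Parameter file: a ``growth`` block plus per-region event vectors.

    Example::

        growth: {baseline_growth: 0.03, baseline_mortality: 0.03,
                 saturation_sensitivity: 0.2, omega_max: 4.6,
                 acidification_enabled: true}
        regions:
          hawaii:
            thresholds: [28.5, 28.75, 29.0, 29.25, 29.5, 29.75]
            trigger_probs: [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
    """
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "regions" not in payload:
        raise ConfigurationError("parameter file needs a 'regions' mapping")
    growth = GrowthParams(**payload.get("growth", {}))
    regions: dict[str, BleachingParams] = {}
    for region, block in payload["regions"].items():
        if "thresholds" not in block:
            raise ConfigurationError(f"region {region}: thresholds required")
        kwargs = {
            k: tuple(block[k])
            for k in ("thresholds", "trigger_probs", "bleaching_factors",
                      "mortality_factors")
            if k in block
        }
        regions[str(region)] = BleachingParams(**kwargs)
    return growth, regions


def write_sst_csv(series: list[MonthlySSTSeries], path) -> None:
    rows = [
        (s.cell_id, int(y), m, round(s.value(int(y), m), 6))
        for s in series
        for y in YEARS
        for m in range(1, 13)
    ]
    pd.DataFrame(rows, columns=["cell_id", "year", "month", "sst_c"]).to_csv(
        path, index=False
    )
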