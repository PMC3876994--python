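"""End-to-end orchestration: scenarios → simulation → valuation → report.

``run_study`` drives the in-memory pipeline on a ``SyntheticBundle`` (or any
equivalently shaped inputs loaded from files); ``run_pipeline`` is the
file-driven entry point used by the CLI; ``write_report`` serializes the
result bundle to CSV/JSON (and optional PNG cover plots) with stable field
ordering so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .carbonate import CarbonateSettings, aragonite_series
from .scenarios import (
    AnnualSeries,
    EmissionsScenario,
    START_YEAR,
    YEARS,
    build_monthly_sst,
    interpolate_annual,
)
from .simulator import (
    BleachingParams,
    CoverTrajectory,
    GrowthParams,
    ReefCell,
    SimulationMode,
    region_weighted_decline,
    run_cell,
)
from .synthetic import SyntheticBundle, make_default_study
from .valuation import (
    PVReport,
    RegionValuationInputs,
    load_region_inputs,
    value_region,
)

log = logging.getLogger("reefval")


@dataclass
class RegionScenarioResult:
    region: str
    scenario: str
    trajectories: list[CoverTrajectory]
    fraction: AnnualSeries  # hardground-weighted fraction of baseline cover


@dataclass
class StudyReport:
    """Everything one study run produces, keyed by region and scenario."""

    results: dict[tuple[str, str], RegionScenarioResult]
    valuations: dict[str, PVReport]
    scenarios: list[str]
    regions: list[str]
    mode: str
    seed: int | None = None

    def result(self, region: str, scenario: str) -> RegionScenarioResult:
        return self.results[(region, scenario)]


@dataclass
class RunConfig:
    """File-driven run configuration.  All referenced files are validated
    before any computation starts."""

    cells: Path
    climatologies: Path
    scenarios: list[Path]
    output_dir: Path
    parameters: Path | None = None
    mode: str = "expected"
    seed: int | None = None
    discount_rate: float = 0.03
    base_year: int = 2007
    acidification: bool = True
    plots: bool = False

    def __post_init__(self) -> None:
        for p in [self.cells, self.climatologies, *self.scenarios] + (
            [self.parameters] if self.parameters else []
        ):
            if not Path(p).is_file():
                raise FileNotFoundError(f"input file not found: {p}")


def _cell_seed(base: int, region: str, cell_id: str, scenario: str) -> int:
    """Stable per-(cell, scenario) stream seed below 2**31."""
    h = np.random.SeedSequence(
        [base] + [ord(c) for c in f"{region}/{cell_id}/{scenario}"]
    )
    return int(h.generate_state(1, np.uint32)[0] % (2**31))


def run_study(
    bundle: SyntheticBundle,
    growth: GrowthParams | None = None,
    mode: str = "expected",
    seed: int | None = None,
    bleach_by_region: dict[str, BleachingParams] | None = None,
    carbonate: CarbonateSettings | None = None,
    valuation_inputs: dict[str, RegionValuationInputs] | None = None,
    bau: str = "bau",
    policy: str = "reduced",
) -> StudyReport:
    """Simulate every cell under every scenario and value the declines.

    ``mode`` is "expected" (deterministic) or "stochastic" (``seed``
    required; each cell × scenario gets an independent derived substream).
    Valuation inputs default to the packaged regional tables for regions
    that have them; other regions are simulated but not valued.
    """
    growth = growth or GrowthParams()
    carbonate = carbonate or CarbonateSettings()
    if valuation_inputs is None:
        valuation_inputs = load_region_inputs()
    if mode == "stochastic" and seed is None:
        raise ValueError("stochastic mode requires a seed")

    regions = bundle.regions
    results: dict[tuple[str, str], RegionScenarioResult] = {}
    for scenario in bundle.scenarios:
        co2 = scenario.co2_series()
        for region in regions:
            anchors = bundle.warming_by_region_scenario.get(
                (region, scenario.name), scenario.warming_anchors
            )
            warming = interpolate_annual(anchors)
            cells = bundle.cells_in(region)
            bleach = (
                bleach_by_region[region]
                if bleach_by_region is not None
                else BleachingParams.for_region(region)
            )
            trajectories = []
            for cell in cells:
                sst = build_monthly_sst(cell.climatology, warming, cell.cell_id)
                annual_sst = AnnualSeries(
                    START_YEAR,
                    float(np.mean(cell.climatology.monthly_mean))
                    + warming.values,
                )
                omega = aragonite_series(co2, annual_sst, carbonate)
                cell_mode = (
                    SimulationMode("expected")
                    if mode == "expected"
                    else SimulationMode(
                        "stochastic",
                        _cell_seed(seed, region, cell.cell_id, scenario.name),
                    )
                )
                traj = run_cell(cell, sst, omega, growth, bleach, cell_mode)
                for year, idx in traj.events:
                    log.info(
                        "event region=%s cell=%s scenario=%s index=%d year=%d",
                        region, cell.cell_id, scenario.name, idx, year,
                    )
                trajectories.append(traj)
            fraction = region_weighted_decline(
                trajectories, [c.hardground_weight for c in cells]
            )
            results[(region, scenario.name)] = RegionScenarioResult(
                region=region,
                scenario=scenario.name,
                trajectories=trajectories,
                fraction=fraction,
            )
            log.info(
                "simulated region=%s scenario=%s cells=%d events=%d",
                region, scenario.name, len(cells),
                sum(len(t.events) for t in trajectories),
            )

    scenario_names = [s.name for s in bundle.scenarios]
    valuations: dict[str, PVReport] = {}
    for region in regions:
        if region not in valuation_inputs:
            continue
        frac = {s: results[(region, s)].fraction for s in scenario_names}
        has_pair = bau in frac and policy in frac
        valuations[region] = value_region(
            valuation_inputs[region],
            frac,
            policy_scenario=policy if has_pair else None,
            bau_scenario=bau if has_pair else None,
        )
    return StudyReport(
        results=results,
        valuations=valuations,
        scenarios=scenario_names,
        regions=regions,
        mode=mode,
        seed=seed,
    )


def run_default_study(
    seed: int, mode: str = "expected", **kwargs
) -> StudyReport:
    """Generate the packaged synthetic study and run it end to end."""
    bundle = make_default_study(seed)
    sim_seed = seed if mode == "stochastic" else None
    return run_study(bundle, mode=mode, seed=sim_seed, **kwargs)


def run_pipeline(config: RunConfig) -> StudyReport:
    """File-driven run: load and validate all inputs, then simulate/value."""
    cells = rio.read_cells_csv(config.cells, rio.read_climatology_csv(config.climatologies))
    scenarios = [rio.read_scenario(p) for p in config.scenarios]
    growth, bleach_by_region = (
        rio.read_parameters(config.parameters)
        if config.parameters
        else (GrowthParams(acidification_enabled=config.acidification), None)
    )
    regions = sorted({c.region for c in cells})
    missing = [
        r for r in regions
        if bleach_by_region is not None and r not in bleach_by_region
    ]
    if missing:
        raise ValueError(f"parameter file lacks thresholds for regions: {missing}")
    bundle = SyntheticBundle(cells=cells, scenarios=scenarios, seed=config.seed or 0)
    inputs = {
        r: RegionValuationInputs(
            region=v.region,
            cs_per_visit=v.cs_per_visit,
            adults=v.adults,
            existence_per_adult=v.existence_per_adult,
            annual_visits=v.annual_visits,
            discount_rate=config.discount_rate,
            base_year=config.base_year,
        )
        for r, v in load_region_inputs().items()
    }
    names = [s.name for s in scenarios]
    bau = "bau" if "bau" in names else names[0]
    policy = "reduced" if "reduced" in names else names[-1]
    report = run_study(
        bundle,
        growth=growth,
        mode=config.mode,
        seed=config.seed if config.mode == "stochastic" else None,
        bleach_by_region=bleach_by_region,
        valuation_inputs=inputs,
        bau=bau,
        policy=policy,
    )
    write_report(report, config.output_dir, plots=config.plots)
    return report


def write_report(report: StudyReport, outdir, plots: bool = False) -> list[Path]:
    """Serialize a study report: cover trajectories, event log, regional
    fraction series, event-year table and valuation summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cover_rows, event_rows, frac_rows = [], [], []
    for (region, scenario), res in sorted(report.results.items()):
        for traj in res.trajectories:
            for y, c in zip(YEARS, traj.annual_cover):
                cover_rows.append((traj.cell_id, region, scenario, int(y),
                                   round(float(c), 6)))
            for y, idx in traj.events:
                event_rows.append((traj.cell_id, region, scenario, idx, y))
        for y, f in zip(YEARS, res.fraction.values):
            frac_rows.append((region, scenario, int(y), round(float(f), 9)))

    p = outdir / "cover_trajectories.csv"
    pd.DataFrame(
        cover_rows, columns=["cell_id", "region", "scenario", "year", "cover_pct"]
    ).to_csv(p, index=False)
    written.append(p)

    p = outdir / "events.csv"
    pd.DataFrame(
        event_rows, columns=["cell_id", "region", "scenario", "event_index", "year"]
    ).to_csv(p, index=False)
    written.append(p)

    p = outdir / "region_fraction.csv"
    pd.DataFrame(
        frac_rows, columns=["region", "scenario", "year", "fraction_of_baseline"]
    ).to_csv(p, index=False)
    written.append(p)

    # mean event year per region × scenario × event index
    ev = pd.DataFrame(
        event_rows, columns=["cell_id", "region", "scenario", "event_index", "year"]
    )
    if len(ev):
        tab = (
            ev.groupby(["region", "scenario", "event_index"])["year"]
            .mean()
            .round(1)
            .reset_index()
            .rename(columns={"year": "mean_year"})
        )
    else:
        tab = pd.DataFrame(columns=["region", "scenario", "event_index", "mean_year"])
    p = outdir / "event_years.csv"
    tab.to_csv(p, index=False)
    written.append(p)

    summary = {}
    for region, pv in sorted(report.valuations.items()):
        entry = {
            "pv_existence_musd": {k: round(v, 3) for k, v in pv.pv_existence.items()},
            "pv_nochange_existence_musd": round(pv.pv_nochange_existence, 3),
            "pct_decline_existence": {
                k: round(v, 3) for k, v in pv.pct_decline_existence.items()
            },
        }
        if pv.pv_recreation is not None:
            entry["pv_recreation_musd"] = {
                k: round(v, 3) for k, v in pv.pv_recreation.items()
            }
            entry["pv_nochange_recreation_musd"] = round(pv.pv_nochange_recreation, 3)
            entry["pct_decline_recreation"] = {
                k: round(v, 3) for k, v in pv.pct_decline_recreation.items()
            }
        if pv.avoided_loss_existence is not None:
            entry["avoided_loss_existence_musd"] = round(pv.avoided_loss_existence, 3)
        if pv.avoided_loss_recreation is not None:
            entry["avoided_loss_recreation_musd"] = round(pv.avoided_loss_recreation, 3)
        summary[region] = entry
    p = outdir / "valuation_summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)

    if plots:
        written.extend(_plot_cover(report, outdir))
    return written


def _plot_cover(report: StudyReport, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for region in report.regions:
        fig, ax = plt.subplots(figsize=(6, 4))
        for scenario in report.scenarios:
            res = report.results[(region, scenario)]
            mean_cover = np.mean(
                [t.annual_cover for t in res.trajectories], axis=0
            )
            ax.plot(YEARS, mean_cover, label=scenario)
        ax.set_xlabel("year")
        ax.set_ylabel("coral cover (%)")
        ax.set_title(region)
        ax.legend()
        p = outdir / f"cover_{region}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
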