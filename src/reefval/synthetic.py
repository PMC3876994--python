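"""Seeded synthetic study inputs: climatologies, cells, warming anchors.

The study's external inputs — gridded historical SST climatologies, per-cell
initial coral cover, hardground-area weights and downscaled warming
anomalies — are emulated here so the full pipeline runs without downloads.
Presets are calibrated only to quantities the analysis anchors on: regional
cell counts (7/2/2 cover cells, 14/9/6 hardground cells for Hawaii/Florida/
Puerto Rico), regional mean initial covers (38.4 / 11.5 / 24.8%), bleaching
thresholds, and the qualitative thermal regime in which Florida and Puerto
Rico warm-season temperatures already sit at their first bleaching threshold
in 2000 while Hawaii sits well below.  Warming anchors are NOT published
values — they are plausible calibration defaults (BAU ≈ +2.5 °C warm-season
warming by 2100, policy ≈ +1.0 °C, consistent with the scenarios' CO₂ gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenarios import (
    BAU_CO2_ANCHORS,
    EmissionsScenario,
    MonthlyClimatology,
    REDUCED_CO2_ANCHORS,
)
from .simulator import ReefCell

#: Stable per-region stream offsets so each region draws an independent,
#: reproducible substream from the same user seed.
_REGION_CODE = {"hawaii": 1, "florida": 2, "puerto_rico": 3}

#: Calibration defaults (not observed values) for warm-season warming (°C above
#: 2000).  Applied identically to every region (anomalies are per-region
#: scalars; no spatial regridding).
DEFAULT_WARMING_ANCHORS: dict[str, list[tuple[int, float]]] = {
    "bau": [(2000, 0.0), (2020, 0.45), (2030, 0.70), (2050, 1.25),
            (2075, 1.90), (2100, 2.50)],
    "reduced": [(2000, 0.0), (2020, 0.35), (2030, 0.50), (2050, 0.75),
                (2075, 0.90), (2100, 1.00)],
}


@dataclass
class RegionPreset:
    """Generator settings for one region's synthetic inputs."""

    region: str
    annual_mean_sst: float
    seasonal_amplitude: float
    monthly_sd: float
    n_cover_cells: int
    n_hardground_cells: int
    initial_cover_range: tuple[float, float]
    warming_anchors_by_scenario: dict[str, list[tuple[int, float]]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_WARMING_ANCHORS.items()
        }
    )
    #: half-width of the uniform per-cell offset added to all 12 monthly means
    jitter_halfwidth: float = 0.15

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0 or self.monthly_sd < 0:
            raise ValueError("amplitude and SD must be nonnegative")
        if self.n_cover_cells > self.n_hardground_cells:
            raise ValueError("cover cells cannot exceed hardground cells")
        lo, hi = self.initial_cover_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("cover range must lie within [0, 100]")


#: Default presets.  Warm-season (August) mean = annual_mean + amplitude:
#: Florida 30.1 °C and Puerto Rico 29.4 °C sit just below their first
#: thresholds (30.2 / 29.5 °C); Hawaii's 27.2 °C sits 1.3 °C below 28.5 °C.
#: Cover ranges are centered on the regional means the projections start from.
DEFAULT_PRESETS: dict[str, RegionPreset] = {
    "hawaii": RegionPreset(
        region="hawaii", annual_mean_sst=25.5, seasonal_amplitude=1.7,
        monthly_sd=0.45, n_cover_cells=7, n_hardground_cells=14,
        initial_cover_range=(35.4, 41.4),
    ),
    "florida": RegionPreset(
        region="florida", annual_mean_sst=27.0, seasonal_amplitude=3.1,
        monthly_sd=0.40, n_cover_cells=2, n_hardground_cells=9,
        initial_cover_range=(9.5, 13.5),
    ),
    "puerto_rico": RegionPreset(
        region="puerto_rico", annual_mean_sst=28.0, seasonal_amplitude=1.4,
        monthly_sd=0.40, n_cover_cells=2, n_hardground_cells=6,
        initial_cover_range=(21.8, 27.8),
    ),
}


@dataclass
class SyntheticBundle:
    """A complete synthetic study: cells for all regions plus scenarios."""

    cells: list[ReefCell]
    scenarios: list[EmissionsScenario]
    seed: int
    warming_by_region_scenario: dict[tuple[str, str], list[tuple[int, float]]] = field(
        default_factory=dict
    )

    def cells_in(self, region: str) -> list[ReefCell]:
        return [c for c in self.cells if c.region == region]

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for c in self.cells:
            if c.region not in seen:
                seen.append(c.region)
        return seen


def _rng(preset: RegionPreset, seed: int, stream: int) -> np.random.Generator:
    code = _REGION_CODE.get(preset.region, 17 + sum(map(ord, preset.region)) % 1000)
    return np.random.default_rng([int(seed), code, stream])


def make_climatology(
    preset: RegionPreset, seed: int, cell_index: int = 0
) -> MonthlyClimatology:
    """Monthly climatology: sinusoid over the year peaking in August, plus a
    small seeded per-cell uniform offset common to all 12 months (so the
    intra-annual shape is identical across a region's cells)."""
    rng = _rng(preset, seed, 100 + cell_index)
    months = np.arange(1, 13)
    means = preset.annual_mean_sst + preset.seasonal_amplitude * np.cos(
        2.0 * np.pi * (months - 8) / 12.0
    )
    means = means + rng.uniform(-preset.jitter_halfwidth, preset.jitter_halfwidth)
    sds = np.full(12, float(preset.monthly_sd))
    return MonthlyClimatology(monthly_mean=means, monthly_sd=sds)


def make_region(preset: RegionPreset, seed: int) -> list[ReefCell]:
    """Generate the region's cover cells: initial cover uniform in the preset
    range, hardground weights log-uniform across one decade."""
    rng = _rng(preset, seed, 0)
    lo, hi = preset.initial_cover_range
    covers = rng.uniform(lo, hi, size=preset.n_cover_cells)
    weights = 10.0 ** rng.uniform(0.0, 1.0, size=preset.n_cover_cells)
    return [
        ReefCell(
            cell_id=f"{preset.region}_{i:02d}",
            region=preset.region,
            initial_cover=float(covers[i]),
            hardground_weight=float(weights[i]),
            climatology=make_climatology(preset, seed, cell_index=i),
        )
        for i in range(preset.n_cover_cells)
    ]


def make_default_study(
    seed: int,
    presets: dict[str, RegionPreset] | None = None,
) -> SyntheticBundle:
    """Three-region, two-scenario synthetic study.

    Scenarios carry the printed CO₂ anchor tables; warming anchors are the
    presets' calibration defaults.  Identical seed → identical bundle.
    """
    presets = presets or DEFAULT_PRESETS
    cells: list[ReefCell] = []
    warming: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for region, preset in presets.items():
        cells.extend(make_region(preset, seed))
        for scen, anchors in preset.warming_anchors_by_scenario.items():
            warming[(region, scen)] = list(anchors)
    any_preset = next(iter(presets.values()))
    scenarios = [
        EmissionsScenario(
            name="bau",
            co2_anchors=list(BAU_CO2_ANCHORS),
            warming_anchors=list(
                any_preset.warming_anchors_by_scenario["bau"]
            ),
        ),
        EmissionsScenario(
            name="reduced",
            co2_anchors=list(REDUCED_CO2_ANCHORS),
            warming_anchors=list(
                any_preset.warming_anchors_by_scenario["reduced"]
            ),
        ),
    ]
    return SyntheticBundle(
        cells=cells,
        scenarios=scenarios,
        seed=int(seed),
        warming_by_region_scenario=warming,
    )
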