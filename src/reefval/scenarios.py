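"""Emissions-scenario expansion: anchor tables to annual and monthly series.

Scenario inputs arrive as sparse anchor points — atmospheric CO₂ (ppm) and
warming relative to the year 2000 (°C) at a handful of calendar years.  The
simulation needs contiguous annual series for 2000–2100 and, per reef cell,
a monthly sea-surface-temperature series built by superimposing the annual
warming on the cell's monthly climatology.  Anchors are linearly
interpolated; outside the anchored range the boundary value is held flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

START_YEAR = 2000
END_YEAR = 2100
N_YEARS = END_YEAR - START_YEAR + 1  # 101
YEARS = np.arange(START_YEAR, END_YEAR + 1)


class ConfigurationError(ValueError):
    """Raised for malformed scenario or parameter inputs."""


@dataclass(frozen=True)
class AnnualSeries:
    """A contiguous annual series covering 2000–2100 inclusive (101 values)."""

    start_year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.start_year != START_YEAR or vals.shape != (N_YEARS,):
            raise ConfigurationError(
                f"annual series must cover {START_YEAR}-{END_YEAR} "
                f"({N_YEARS} values); got start={self.start_year}, "
                f"n={vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("annual series contains non-finite values")

    def value(self, year: int) -> float:
        if not START_YEAR <= year <= END_YEAR:
            raise ValueError(f"year {year} outside {START_YEAR}-{END_YEAR}")
        return float(self.values[year - START_YEAR])


@dataclass(frozen=True)
class MonthlyClimatology:
    """Per-cell monthly SST normals: 12 means and 12 interannual SDs (°C)."""

    monthly_mean: np.ndarray
    monthly_sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.monthly_mean, dtype=float)
        sd = np.asarray(self.monthly_sd, dtype=float)
        object.__setattr__(self, "monthly_mean", mean)
        object.__setattr__(self, "monthly_sd", sd)
        if mean.shape != (12,) or sd.shape != (12,):
            raise ConfigurationError("climatology needs 12 means and 12 SDs")
        if np.any(sd < 0):
            raise ConfigurationError("interannual SDs must be nonnegative")
        if np.any(mean < -2.0) or np.any(mean > 40.0):
            raise ConfigurationError("monthly means outside [-2, 40] °C")

    @property
    def warmest_month(self) -> int:
        """1-based index of the climatologically warmest month."""
        return int(np.argmax(self.monthly_mean)) + 1


@dataclass(frozen=True)
class MonthlySSTSeries:
    """Projected monthly SSTs for one cell, 12 × 101 values, years 2000–2100.

    Values are ordered year by year, months 1–12 within each year.
    """

    cell_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (12 * N_YEARS,):
            raise ConfigurationError(
                f"monthly SST series must have {12 * N_YEARS} values"
            )

    def value(self, year: int, month: int) -> float:
        if not 1 <= month <= 12:
            raise ValueError(f"month {month} outside 1-12")
        if not START_YEAR <= year <= END_YEAR:
            raise ValueError(f"year {year} outside {START_YEAR}-{END_YEAR}")
        return float(self.values[(year - START_YEAR) * 12 + (month - 1)])


@dataclass
class EmissionsScenario:
    """Named scenario: CO₂ anchors (year, ppm) and warming anchors (year, °C
    above 2000).  ``climate_sensitivity`` (°C per CO₂ doubling) is metadata
    describing how the anchors were produced, not an input to any formula."""

    name: str
    co2_anchors: list[tuple[int, float]]
    warming_anchors: list[tuple[int, float]]
    climate_sensitivity: float = 3.0

    def __post_init__(self) -> None:
        self.co2_anchors = _check_anchors(self.co2_anchors, "co2")
        self.warming_anchors = _check_anchors(self.warming_anchors, "warming")
        if any(ppm <= 0 for _, ppm in self.co2_anchors):
            raise ConfigurationError("CO2 anchors must be positive ppm")
        w2000 = dict(self.warming_anchors).get(START_YEAR)
        if w2000 is not None and abs(w2000) > 1e-12:
            raise ConfigurationError("warming anchor at 2000 must be 0 °C")

    def co2_series(self) -> AnnualSeries:
        return interpolate_annual(self.co2_anchors)

    def warming_series(self) -> AnnualSeries:
        return interpolate_annual(self.warming_anchors)


def _check_anchors(
    anchors: list[tuple[int, float]], label: str
) -> list[tuple[int, float]]:
    anchors = [(int(y), float(v)) for y, v in anchors]
    if len(anchors) < 2:
        raise ConfigurationError(f"{label}: need at least 2 anchors")
    years = [y for y, _ in anchors]
    if len(set(years)) != len(years):
        raise ConfigurationError(f"{label}: duplicate anchor years")
    return sorted(anchors)


def interpolate_annual(anchors: list[tuple[int, float]]) -> AnnualSeries:
    """Piecewise-linear interpolation of (year, value) anchors onto every
    integer year 2000–2100; boundary values are held flat outside the
    anchored range."""
    anchors = _check_anchors(anchors, "anchors")
    ys = np.array([y for y, _ in anchors], dtype=float)
    vs = np.array([v for _, v in anchors], dtype=float)
    # np.interp clamps to the end values, which is exactly the flat padding
    values = np.interp(YEARS.astype(float), ys, vs)
    return AnnualSeries(START_YEAR, values)


def build_monthly_sst(
    climatology: MonthlyClimatology,
    warming: AnnualSeries,
    cell_id: str = "cell",
) -> MonthlySSTSeries:
    """Superimpose annual warming on the monthly climatology.

    SST(year, month) = monthly_mean[month] + warming(year).  Interannual
    variability is not added here; the climatology's monthly SDs travel
    alongside and are consumed by the bleaching-event module.
    """
    vals = (climatology.monthly_mean[None, :] + warming.values[:, None]).ravel()
    return MonthlySSTSeries(cell_id=cell_id, values=vals)


#: Printed CO₂ anchor tables for the two study scenarios (ppm).
BAU_CO2_ANCHORS: list[tuple[int, float]] = [
    (2000, 369.0), (2030, 443.0), (2050, 519.0), (2075, 639.0), (2100, 785.0),
]
REDUCED_CO2_ANCHORS: list[tuple[int, float]] = [
    (2000, 369.0), (2030, 421.0), (2050, 426.0), (2075, 423.0), (2100, 427.0),
]
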