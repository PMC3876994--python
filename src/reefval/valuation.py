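"""Benefit-transfer valuation of coral-cover change.

Two service categories are valued, and deliberately never summed into a
"total reef value":

* recreational use — consumer surplus per reef visit (unit value transferred
  as the mean of published US travel-cost and contingent-valuation studies)
  times annual visits;
* existence value — willingness to pay per adult resident to avoid reef
  loss, times the adult population.

Both value streams are assumed proportional to regional coral cover
(fraction of year-2000 baseline), discounted to a 2007 base year at 3%/yr
and summed over 2000–2100.  The avoided loss of a mitigation scenario is
the difference of the two scenario present values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .scenarios import AnnualSeries, N_YEARS, START_YEAR, YEARS


@dataclass(frozen=True)
class UnitValueStudy:
    """One published per-day consumer-surplus estimate (US 2007$)."""

    label: str
    method: str  # travel_cost | contingent_valuation
    cs_per_day: float

    def __post_init__(self) -> None:
        if self.cs_per_day <= 0:
            raise ValueError("consumer surplus per day must be positive")
        if self.method not in ("travel_cost", "contingent_valuation"):
            raise ValueError(f"unknown valuation method {self.method!r}")


@dataclass(frozen=True)
class RegionValuationInputs:
    """Baseline valuation inputs for one region (US 2007$).

    annual_visits : million reef visits/yr; None when no defensible estimate
        exists (recreation is then structurally unavailable, not zero)
    cs_per_visit : $/visit consumer surplus
    adults : million adult residents
    existence_per_adult : $/adult/yr willingness to pay
    """

    region: str
    cs_per_visit: float
    adults: float
    existence_per_adult: float
    annual_visits: float | None = None
    discount_rate: float = 0.03
    base_year: int = 2007

    def __post_init__(self) -> None:
        for name in ("cs_per_visit", "adults", "existence_per_adult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.annual_visits is not None and self.annual_visits < 0:
            raise ValueError("annual visits must be nonnegative")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be nonnegative")
        if not 2000 <= self.base_year <= 2100:
            raise ValueError("base year outside 2000-2100")


@dataclass
class ValueStream:
    """Annual value streams ($M/yr, 2000–2100) for one region × scenario."""

    region: str
    scenario: str
    annual_existence: np.ndarray
    annual_recreation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("annual_existence", "annual_recreation"):
            vals = getattr(self, name)
            if vals is None:
                continue
            vals = np.asarray(vals, dtype=float)
            setattr(self, name, vals)
            if vals.shape != (N_YEARS,):
                raise ValueError(f"{name} must have {N_YEARS} values")
            if np.any(vals < 0):
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PVReport:
    """Present values ($M) and scenario comparisons for one region."""

    region: str
    pv_existence: dict[str, float]
    pv_nochange_existence: float
    pct_decline_existence: dict[str, float]
    pv_recreation: dict[str, float] | None = None
    pv_nochange_recreation: float | None = None
    pct_decline_recreation: dict[str, float] | None = None
    avoided_loss_existence: float | None = None
    avoided_loss_recreation: float | None = None


def mean_unit_value(studies: list[UnitValueStudy]) -> float:
    """Arithmetic mean of the per-day consumer-surplus values ($/visit).

    Full precision; round to cents for reporting."""
    if not studies:
        raise ValueError("need at least one study")
    return float(np.mean([s.cs_per_day for s in studies]))


def unit_value_ci95(studies: list[UnitValueStudy]) -> tuple[float, float]:
    """Normal-approximation 95% CI of the mean: mean ± 1.96·s/√n with the
    n−1 sample SD (this is the formula the printed interval uses)."""
    if len(studies) < 2:
        raise ValueError("need at least two studies for a CI")
    vals = np.array([s.cs_per_day for s in studies], dtype=float)
    half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
    return float(vals.mean() - half), float(vals.mean() + half)


def baseline_annual_values(
    inputs: RegionValuationInputs,
) -> tuple[float | None, float]:
    """Baseline ($M/yr) recreation and existence values.

    Recreation is None when the region has no visit estimate."""
    recreation = (
        None
        if inputs.annual_visits is None
        else inputs.annual_visits * inputs.cs_per_visit
    )
    existence = inputs.adults * inputs.existence_per_adult
    return recreation, existence


def scale_by_cover(baseline: float, fraction_series: AnnualSeries) -> np.ndarray:
    """Annual value stream: baseline scaled by the cover fraction-of-baseline
    (equal percentage loss in value per percentage loss in cover)."""
    frac = fraction_series.values
    if np.any(frac < 0):
        raise ValueError("cover fractions must be nonnegative")
    return baseline * frac


def present_value(stream, rate: float, base_year: int = 2007) -> float:
    """Σ over 2000–2100 of value(y)·(1+rate)^(base_year − y).

    Years before the base year compound upward; rate 0 is a plain sum."""
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    stream = np.asarray(stream, dtype=float)
    if stream.shape != (N_YEARS,):
        raise ValueError(f"stream must have {N_YEARS} values")
    factors = (1.0 + rate) ** (base_year - YEARS)
    return float(np.sum(stream * factors))


def avoided_loss(pv_policy: float, pv_bau: float) -> float:
    """Present-value loss avoided by the policy scenario relative to BAU."""
    return pv_policy - pv_bau


def percent_decline_vs_nochange(pv_scenario: float, pv_nochange: float) -> float:
    """Percent decline of a scenario's PV relative to the no-decline PV."""
    if pv_nochange <= 0:
        raise ValueError("no-change PV must be positive")
    return 100.0 * (1.0 - pv_scenario / pv_nochange)


def value_region(
    inputs: RegionValuationInputs,
    fraction_by_scenario: dict[str, AnnualSeries],
    policy_scenario: str | None = None,
    bau_scenario: str | None = None,
) -> PVReport:
    """Full valuation for one region across scenarios.

    ``fraction_by_scenario`` maps scenario name → fraction-of-baseline cover
    series.  When ``policy_scenario`` and ``bau_scenario`` are given, avoided
    losses (policy PV − BAU PV) are included.
    """
    recreation, existence = baseline_annual_values(inputs)
    ones = AnnualSeries(START_YEAR, np.ones(N_YEARS))

    def pv_of(baseline: float, frac: AnnualSeries) -> float:
        return present_value(
            scale_by_cover(baseline, frac), inputs.discount_rate, inputs.base_year
        )

    pv_nc_ex = pv_of(existence, ones)
    pv_ex = {s: pv_of(existence, f) for s, f in fraction_by_scenario.items()}
    report = PVReport(
        region=inputs.region,
        pv_existence=pv_ex,
        pv_nochange_existence=pv_nc_ex,
        pct_decline_existence={
            s: percent_decline_vs_nochange(pv, pv_nc_ex) for s, pv in pv_ex.items()
        },
    )
    if recreation is not None:
        pv_nc_rec = pv_of(recreation, ones)
        pv_rec = {s: pv_of(recreation, f) for s, f in fraction_by_scenario.items()}
        report.pv_recreation = pv_rec
        report.pv_nochange_recreation = pv_nc_rec
        report.pct_decline_recreation = {
            s: percent_decline_vs_nochange(pv, pv_nc_rec)
            for s, pv in pv_rec.items()
        }
    if policy_scenario is not None and bau_scenario is not None:
        report.avoided_loss_existence = avoided_loss(
            report.pv_existence[policy_scenario],
            report.pv_existence[bau_scenario],
        )
        if report.pv_recreation is not None:
            report.avoided_loss_recreation = avoided_loss(
                report.pv_recreation[policy_scenario],
                report.pv_recreation[bau_scenario],
            )
    return report


def load_unit_value_studies() -> list[UnitValueStudy]:
    """Packaged per-day consumer-surplus study table."""
    text = resources.files("reefval.data").joinpath("unit_values.csv").read_text()
    return [
        UnitValueStudy(
            label=row["label"],
            method=row["method"],
            cs_per_day=float(row["cs_per_day"]),
        )
        for row in csv.DictReader(text.splitlines())
    ]


def load_region_inputs(
    cs_per_visit: float | None = None,
) -> dict[str, RegionValuationInputs]:
    """Packaged regional valuation inputs.

    ``cs_per_visit`` defaults to the mean of the packaged study table (the
    same transferred unit value is applied to every region)."""
    if cs_per_visit is None:
        cs_per_visit = mean_unit_value(load_unit_value_studies())
    text = resources.files("reefval.data").joinpath("region_values.csv").read_text()
    out: dict[str, RegionValuationInputs] = {}
    for row in csv.DictReader(text.splitlines()):
        visits = row["annual_visits_million"]
        out[row["region"]] = RegionValuationInputs(
            region=row["region"],
            cs_per_visit=cs_per_visit,
            adults=float(row["adults_million"]),
            existence_per_adult=float(row["existence_per_adult"]),
            annual_visits=float(visits) if visits else None,
        )
    return out
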