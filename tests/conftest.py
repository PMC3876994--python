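import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

from reefval import (
    AnnualSeries,
    BleachingParams,
    GrowthParams,
    MonthlyClimatology,
    ReefCell,
    build_monthly_sst,
)
from reefval.scenarios import N_YEARS, START_YEAR


def flat_climatology(mean=27.0, sd=0.5, warm_month=8, amplitude=0.0):
    """Climatology with an optional single warm month standing out."""
    means = np.full(12, float(mean))
    means[warm_month - 1] += amplitude
    return MonthlyClimatology(monthly_mean=means, monthly_sd=np.full(12, float(sd)))


def constant_series(value):
    return AnnualSeries(START_YEAR, np.full(N_YEARS, float(value)))


def linear_warming(total_by_2100):
    return AnnualSeries(START_YEAR, np.linspace(0.0, total_by_2100, N_YEARS))


@pytest.fixture
def cold_cell():
    """Cell whose warm-season temperature never approaches any threshold."""
    clim = flat_climatology(mean=20.0, sd=0.3, amplitude=1.0)
    return ReefCell(
        cell_id="cold", region="hawaii", initial_cover=38.4,
        hardground_weight=1.0, climatology=clim,
    )


@pytest.fixture
def hawaii_bleach():
    return BleachingParams.for_region("hawaii")


@pytest.fixture
def default_growth():
    return GrowthParams()


def sst_for(cell, warming):
    return build_monthly_sst(cell.climatology, warming, cell.cell_id)
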