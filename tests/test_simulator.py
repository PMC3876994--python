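"""Coral-cover simulator: growth arithmetic, event machinery, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reefval import (
    BleachingParams,
    GrowthParams,
    MonthlyClimatology,
    ReefCell,
    SimulationMode,
    apply_bleaching,
    cumulative_event_probability,
    detect_next_event,
    exceedance_probability,
    growth_modifier,
    net_monthly_rate,
    region_weighted_decline,
    run_cell,
)
from reefval.scenarios import AnnualSeries, N_YEARS, START_YEAR
from reefval.simulator import CoverTrajectory, REGION_THRESHOLDS

from conftest import constant_series, flat_climatology, linear_warming, sst_for

EXPECTED = SimulationMode()


class TestGrowthArithmetic:
    @pytest.mark.parametrize(
        "omega,expected",
        [(4.6, 1.0), (3.6, 0.8), (0.1, 0.1), (5.5, 1.0)],
        ids=["max-growth", "one-unit-below", "clamped-low", "above-max"],
    )
    def test_growth_modifier(self, omega, expected, default_growth):
        assert growth_modifier(omega, default_growth) == pytest.approx(expected)

    def test_growth_modifier_rejects_nonpositive_omega(self, default_growth):
        with pytest.raises(ValueError):
            growth_modifier(0.0, default_growth)

    def test_net_rate_zero_at_max_omega(self, default_growth):
        assert net_monthly_rate(4.6, default_growth) == pytest.approx(0.0)

    def test_net_rate_one_unit_below(self, default_growth):
        # (0.03 × 0.8 − 0.03)/12 = −5e-4 per month
        assert net_monthly_rate(3.6, default_growth) == pytest.approx(-5e-4)

    def test_acidification_flag_disables_omega_pathway(self):
        params = GrowthParams(acidification_enabled=False)
        assert net_monthly_rate(1.5, params) == 0.0
        assert net_monthly_rate(4.6, params) == 0.0


class TestEventProbabilities:
    def test_mean_at_threshold_gives_half(self):
        assert exceedance_probability(28.0, 28.0, 0.5) == pytest.approx(0.5)

    def test_standard_normal_quantile(self):
        assert exceedance_probability(28.0, 28.0 - 1.6449 * 0.4, 0.4) == pytest.approx(
            0.05, abs=1e-4
        )

    def test_zero_sd_degenerates_to_indicator(self):
        assert exceedance_probability(28.0, 27.9, 0.0) == 0.0
        assert exceedance_probability(28.0, 28.1, 0.0) == 1.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            exceedance_probability(28.0, 27.0, -0.1)

    @pytest.mark.parametrize(
        "ps,expected",
        [([0.5], 0.5), ([0.1, 0.1, 0.1], 0.271), ([0.0, 0.0], 0.0)],
    )
    def test_cumulative_probability(self, ps, expected):
        assert cumulative_event_probability(ps) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_cumulative_monotone_as_years_accrue(self, ps):
        cums = [cumulative_event_probability(ps[: k + 1]) for k in range(len(ps))]
        assert all(b >= a - 1e-12 for a, b in zip(cums, cums[1:]))


class TestDetectNextEvent:
    def make(self, clim_mean, sd, warming, threshold1=28.5):
        clim = flat_climatology(mean=clim_mean - 1.0, sd=sd, amplitude=1.0)
        params = BleachingParams(
            thresholds=tuple(threshold1 + 0.2 * k for k in range(6))
        )
        cell = ReefCell("c", "hawaii", 30.0, 1.0, clim)
        return sst_for(cell, warming), clim, params

    def test_mean_at_threshold_fires_first_year(self):
        sst, clim, params = self.make(28.5, 0.4, constant_series(0.0))
        year = detect_next_event(sst, clim, params, 1, 2000, EXPECTED)
        assert year == 2000  # yearly p = 0.5 meets the 0.5 trigger at once

    def test_three_sd_below_never_fires(self):
        sst, clim, params = self.make(28.5 - 3 * 0.4, 0.4, constant_series(0.0))
        assert detect_next_event(sst, clim, params, 1, 2000, EXPECTED) is None

    def test_fire_year_monotone_in_trigger_probability(self):
        warming = linear_warming(2.0)
        years = []
        for trigger in (0.9, 0.5, 0.2):
            clim = flat_climatology(mean=26.5, sd=0.4, amplitude=1.0)
            params = BleachingParams(
                thresholds=tuple(28.5 + 0.2 * k for k in range(6)),
                trigger_probs=(trigger,) * 6,
            )
            cell = ReefCell("c", "hawaii", 30.0, 1.0, clim)
            years.append(
                detect_next_event(sst_for(cell, warming), clim, params, 1, 2000, EXPECTED)
            )
        assert years[0] >= years[1] >= years[2]

    def test_fire_year_monotone_in_thresholds_and_warming(self):
        """Uniformly raising thresholds never fires earlier; uniformly adding
        warming never fires later."""
        clim = flat_climatology(mean=26.5, sd=0.4, amplitude=1.0)
        cell = ReefCell("c", "hawaii", 30.0, 1.0, clim)
        base = BleachingParams(thresholds=tuple(28.5 + 0.2 * k for k in range(6)))
        raised = BleachingParams(thresholds=tuple(29.0 + 0.2 * k for k in range(6)))
        for total in (1.5, 2.0, 3.0):
            w = linear_warming(total)
            y_base = detect_next_event(sst_for(cell, w), clim, base, 1, 2000, EXPECTED)
            y_raised = detect_next_event(sst_for(cell, w), clim, raised, 1, 2000, EXPECTED)
            assert y_raised is None or (y_base is not None and y_raised >= y_base)
        w_lo, w_hi = linear_warming(1.5), linear_warming(2.5)
        y_lo = detect_next_event(sst_for(cell, w_lo), clim, base, 1, 2000, EXPECTED)
        y_hi = detect_next_event(sst_for(cell, w_hi), clim, base, 1, 2000, EXPECTED)
        assert y_lo is None or (y_hi is not None and y_hi <= y_lo)

    def test_invalid_event_index_rejected(self):
        sst, clim, params = self.make(28.5, 0.4, constant_series(0.0))
        with pytest.raises(ValueError):
            detect_next_event(sst, clim, params, 7, 2000, EXPECTED)


class TestApplyBleaching:
    @pytest.mark.parametrize(
        "cover,index,expected",
        [(100.0, 1, 85.0), (100.0, 3, 85.0), (0.0, 1, 0.0)],
        ids=["event1-bf.5-mf.3", "event3-bf.3-mf.5", "absorbing-zero"],
    )
    def test_expected_mode_loss(self, cover, index, expected, hawaii_bleach):
        assert apply_bleaching(cover, index, hawaii_bleach, EXPECTED) == pytest.approx(
            expected
        )

    def test_stochastic_mode_is_bernoulli(self, hawaii_bleach):
        rng = np.random.default_rng(0)
        mode = SimulationMode("stochastic", seed=0)
        outcomes = {
            apply_bleaching(100.0, 1, hawaii_bleach, mode, rng) for _ in range(200)
        }
        assert outcomes == {100.0, 70.0}  # untouched or full mf=0.3 loss


class TestRunCell:
    def test_steady_state_when_no_stress(self, cold_cell, hawaii_bleach, default_growth):
        traj = run_cell(
            cold_cell, sst_for(cold_cell, constant_series(0.0)),
            constant_series(4.6), default_growth, hawaii_bleach,
        )
        assert traj.events == []
        np.testing.assert_allclose(traj.annual_cover, 38.4, rtol=1e-12)

    def test_acidification_decay_matches_closed_form(
        self, cold_cell, hawaii_bleach, default_growth
    ):
        traj = run_cell(
            cold_cell, sst_for(cold_cell, constant_series(0.0)),
            constant_series(3.6), default_growth, hawaii_bleach,
        )
        rate = net_monthly_rate(3.6, default_growth)
        expected = 38.4 * (1.0 + rate) ** 1212
        assert traj.events == []
        assert traj.cover(2100) == pytest.approx(expected, rel=1e-9)
        assert traj.cover(2100) == pytest.approx(20.9, abs=0.1)

    def test_six_events_ladder_with_zero_variance(self, default_growth):
        """Step the warm month above all six thresholds: one event per year,
        escalating indices, total loss = Π(1 − bf·mf)."""
        clim = flat_climatology(mean=27.0, sd=0.0, amplitude=1.0)
        params = BleachingParams.for_region("hawaii")
        cell = ReefCell("c", "hawaii", 50.0, 1.0, clim)
        step = np.zeros(N_YEARS)
        step[10:] = 3.0  # from 2010: warm month at 31 °C > all thresholds
        traj = run_cell(
            cell, sst_for(cell, AnnualSeries(START_YEAR, step)),
            constant_series(4.6), default_growth, params,
        )
        assert [idx for _, idx in traj.events] == [1, 2, 3, 4, 5, 6]
        assert [y for y, _ in traj.events] == list(range(2010, 2016))
        expected = 50.0 * np.prod(
            1.0 - np.array(params.bleaching_factors) * np.array(params.mortality_factors)
        )
        assert traj.cover(2100) == pytest.approx(expected, rel=1e-12)

    def test_cover_stays_in_bounds_and_caps_at_100(self, hawaii_bleach):
        clim = flat_climatology(mean=20.0, sd=0.3, amplitude=1.0)
        cell = ReefCell("c", "hawaii", 99.5, 1.0, clim)
        growth = GrowthParams(baseline_growth=0.10, baseline_mortality=0.01)
        traj = run_cell(
            cell, sst_for(cell, constant_series(0.0)),
            constant_series(4.6), growth, hawaii_bleach,
        )
        assert np.all(traj.annual_cover <= 100.0)
        assert traj.cover(2100) == 100.0

    def test_event_years_strictly_increasing_and_indices_consecutive(
        self, default_growth
    ):
        clim = flat_climatology(mean=27.5, sd=0.4, amplitude=1.0)
        cell = ReefCell("c", "hawaii", 40.0, 1.0, clim)
        traj = run_cell(
            cell, sst_for(cell, linear_warming(2.5)),
            constant_series(4.0), default_growth,
            BleachingParams.for_region("hawaii"),
        )
        years = [y for y, _ in traj.events]
        indices = [i for _, i in traj.events]
        assert len(traj.events) >= 3
        assert years == sorted(set(years))
        assert indices == list(range(1, len(indices) + 1))

    def test_stochastic_run_reproducible_under_seed(self, default_growth):
        clim = flat_climatology(mean=27.5, sd=0.4, amplitude=1.0)
        cell = ReefCell("c", "hawaii", 40.0, 1.0, clim)
        sst = sst_for(cell, linear_warming(2.5))
        args = (cell, sst, constant_series(4.0), default_growth,
                BleachingParams.for_region("hawaii"))
        t1 = run_cell(*args, SimulationMode("stochastic", seed=42))
        t2 = run_cell(*args, SimulationMode("stochastic", seed=42))
        t3 = run_cell(*args, SimulationMode("stochastic", seed=43))
        np.testing.assert_array_equal(t1.annual_cover, t2.annual_cover)
        assert t1.events == t2.events
        assert t1.events != t3.events or not np.array_equal(
            t1.annual_cover, t3.annual_cover
        )


class TestRegionWeightedDecline:
    @staticmethod
    def traj(cell_id, series):
        return CoverTrajectory(cell_id, np.asarray(series, dtype=float))

    def test_single_cell_is_identity(self):
        cov = np.linspace(40.0, 10.0, N_YEARS)
        frac = region_weighted_decline([self.traj("a", cov)], [2.0])
        np.testing.assert_allclose(frac.values, cov / 40.0, rtol=1e-12)
        assert frac.value(2000) == 1.0

    def test_equal_weights_symmetry(self):
        full = np.full(N_YEARS, 30.0)
        gone = np.concatenate([[30.0], np.zeros(N_YEARS - 1)])
        frac = region_weighted_decline(
            [self.traj("a", full), self.traj("b", gone)], [1.0, 1.0]
        )
        assert frac.value(2050) == pytest.approx(0.5)

    def test_weighted_mean_arithmetic(self):
        a = np.full(N_YEARS, 40.0); a[1:] = 32.0   # fraction 0.8
        b = np.full(N_YEARS, 10.0); b[1:] = 4.0    # fraction 0.4
        frac = region_weighted_decline(
            [self.traj("a", a), self.traj("b", b)], [3.0, 1.0]
        )
        assert frac.value(2050) == pytest.approx(0.7)

    def test_zero_baseline_with_positive_weight_rejected(self):
        with pytest.raises(ValueError):
            region_weighted_decline([self.traj("a", np.zeros(N_YEARS))], [1.0])

    def test_weight_validation(self):
        t = self.traj("a", np.full(N_YEARS, 10.0))
        with pytest.raises(ValueError):
            region_weighted_decline([t], [0.0])
        with pytest.raises(ValueError):
            region_weighted_decline([t], [-1.0])


class TestParamValidation:
    def test_thresholds_must_escalate(self):
        with pytest.raises(ValueError):
            BleachingParams(thresholds=(29.0, 28.5, 29.5, 30.0, 30.5, 31.0))

    def test_factors_in_unit_interval(self):
        with pytest.raises(ValueError):
            BleachingParams(
                thresholds=REGION_THRESHOLDS["hawaii"],
                bleaching_factors=(1.5, 0.4, 0.3, 0.3, 0.3, 0.3),
            )

    def test_florida_defaults_continue_ladder(self):
        fl = BleachingParams.for_region("florida")
        assert fl.thresholds == (30.2, 30.4, 30.6, 30.8, 31.0, 31.2)
        steps = np.diff(fl.thresholds)
        np.testing.assert_allclose(steps, 0.2)

    def test_stochastic_mode_requires_seed(self):
        with pytest.raises(ValueError):
            SimulationMode("stochastic")
        with pytest.raises(ValueError):
            SimulationMode("expected", seed=1)
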