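"""Gas normalization, sensor fusion, smoothing, and cycle segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digesterkit.gas import (
    DailyCycle,
    FeedingSchedule,
    GasTimeSeries,
    align_fraction,
    daily_yield,
    magnus_svp,
    methane_rate,
    normalize_volume,
    running_mean,
    segment_cycles,
)


def _series(time, flow, frac, temp=0.0, pres=1013.25, sat=False):
    n = len(time)
    return GasTimeSeries(
        time=np.asarray(time, dtype=float),
        flow=np.asarray(flow, dtype=float),
        ch4_fraction=np.asarray(frac, dtype=float),
        temperature_c=np.full(n, temp),
        pressure_hpa=np.full(n, pres),
        water_saturated=np.full(n, sat),
    )


class TestNormalizeVolume:
    def test_identity_at_normal_dry_conditions(self):
        assert normalize_volume(100.0, 0.0, 1013.25, False) == pytest.approx(100.0)

    def test_zero_flow_stays_zero(self):
        assert normalize_volume(0.0, 37.0, 990.0, True) == 0.0

    def test_saturated_stream_at_37C(self):
        # Magnus: p_w(37) = 6.1094*exp(17.625*37/280.04) = 62.71 hPa, then
        # (1013.25-62.71)/1013.25 * 273.15/310.15 = 0.82620
        assert magnus_svp(37.0) == pytest.approx(62.71, abs=0.01)
        out = normalize_volume(100.0, 37.0, 1013.25, True)
        assert out == pytest.approx(82.62, abs=0.01)

    @given(
        t1=st.floats(0.0, 59.0),
        dt=st.floats(0.5, 20.0),
        p=st.floats(900.0, 1100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_temperature(self, t1, dt, p):
        lo = normalize_volume(50.0, t1, p, False)
        hi = normalize_volume(50.0, t1 + dt, p, False)
        assert hi < lo

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(flow=-1.0, temperature_c=20.0, pressure_hpa=1000.0, water_saturated=False), "flow"),
            (dict(flow=1.0, temperature_c=-300.0, pressure_hpa=1000.0, water_saturated=False), "temperature"),
            (dict(flow=1.0, temperature_c=20.0, pressure_hpa=-5.0, water_saturated=False), "pressure"),
            (dict(flow=1.0, temperature_c=90.0, pressure_hpa=100.0, water_saturated=True), "pressure"),
        ],
    )
    def test_rejects_nonphysical_inputs_naming_field(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            normalize_volume(**kwargs)


class TestMethaneRate:
    def test_product_of_flow_and_fraction(self):
        s = _series([0, 1, 2], [10, 10, 10], [0.5, 0.5, 0.5])
        np.testing.assert_allclose(methane_rate(s), [5.0, 5.0, 5.0])

    def test_zero_fraction_gives_zero_rate(self):
        s = _series([0, 1, 2], [10, 20, 30], [0.0, 0.0, 0.0])
        assert not methane_rate(s).any()

    def test_daily_integral_matches_hand_value(self):
        # 2600 mL/day at 55% CH4 -> 1430 mL CH4/day
        t = np.arange(1441.0)
        s = _series(t, np.full(t.size, 2600.0 / 1440.0), np.full(t.size, 0.55))
        rate = methane_rate(s)
        total = np.trapezoid(rate, t)
        assert total == pytest.approx(1430.0, rel=1e-6)

    def test_alignment_interpolates_to_flow_grid(self):
        s = _series([0, 1, 2], [10, 10, 10], [0, 0, 0])
        rate = methane_rate(s, ch4_time=[-1, 3], ch4_fraction=[0.4, 0.4])
        np.testing.assert_allclose(rate, 4.0)

    def test_extrapolation_refused(self):
        s = _series([0, 1, 2], [10, 10, 10], [0, 0, 0])
        with pytest.raises(ValueError, match="overlap"):
            methane_rate(s, ch4_time=[0.5, 1.5], ch4_fraction=[0.5, 0.5])


class TestRunningMean:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.3)
        np.testing.assert_allclose(running_mean(x, 15.0), x)

    def test_three_point_window_example(self):
        out = running_mean(np.array([0.0, 3.0, 0.0]), 3.0)
        np.testing.assert_allclose(out, [1.5, 1.0, 1.5])

    def test_step_series_matches_truncated_window_oracle(self):
        x = np.array([0.0] * 10 + [6.0] * 10)
        window = 5.0
        out = running_mean(x, window)
        half = 2
        oracle = np.array(
            [x[max(0, i - half) : i + half + 1].mean() for i in range(x.size)]
        )
        np.testing.assert_allclose(out, oracle)

    def test_envelope_and_approximate_mean_preservation(self, rng):
        x = rng.normal(0, 1, 2000)
        out = running_mean(x, 15.0)
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12
        # truncated edges perturb the global mean only at O(window/n)
        assert abs(out.mean() - x.mean()) < 0.05 * x.std()

    def test_window_below_sampling_interval_passes_through(self, caplog):
        x = np.array([1.0, 2.0, 3.0])
        out = running_mean(x, 0.4, times=[0.0, 1.0, 2.0])
        np.testing.assert_allclose(out, x)


class TestSegmentCycles:
    def _schedule(self, feeds):
        return FeedingSchedule(np.asarray(feeds, float), 4.0, 30.0, 1.7)

    def test_two_days_two_full_cycles(self):
        t = np.arange(0.0, 2880.0, 10.0)
        s = _series(t, np.ones(t.size), np.full(t.size, 0.5))
        cycles = segment_cycles(s, self._schedule([0.0, 1440.0]))
        assert len(cycles) == 2
        assert all(c.t_rel[-1] < 1440.0 for c in cycles)

    def test_pre_feed_data_excluded(self):
        t = np.arange(0.0, 1440.0, 10.0)
        s = _series(t, np.ones(t.size), np.full(t.size, 0.5))
        (cycle,) = segment_cycles(s, self._schedule([100.0, 1540.0]))
        assert cycle.t_rel[0] == 0.0
        assert cycle.t_rel.size == ((t >= 100.0).sum())

    def test_constant_rate_integrates_to_1440(self):
        t = np.arange(0.0, 1441.0)
        s = _series(t, np.ones(t.size), np.ones(t.size))
        (cycle, *_) = segment_cycles(s, self._schedule([0.0, 1441.0]))
        assert cycle.ch4_cumulative[-1] == pytest.approx(1440.0, rel=1e-3)

    def test_every_in_span_sample_in_exactly_one_cycle(self):
        t = np.arange(0.0, 4320.0, 7.0)
        s = _series(t, np.ones(t.size), np.full(t.size, 0.5))
        cycles = segment_cycles(s, self._schedule([0.0, 1440.0, 2880.0]))
        total = sum(len(c) for c in cycles)
        assert total == t.size

    def test_overlapping_feeds_rejected(self):
        t = np.arange(0.0, 1440.0, 10.0)
        s = _series(t, np.ones(t.size), np.full(t.size, 0.5))
        with pytest.raises(ValueError, match="60 min"):
            segment_cycles(s, self._schedule([0.0, 30.0]))

    def test_internal_gap_flags_incomplete(self):
        t = np.concatenate([np.arange(0.0, 300.0, 10.0), np.arange(400.0, 1440.0, 10.0)])
        s = _series(t, np.ones(t.size), np.full(t.size, 0.5))
        (cycle,) = segment_cycles(s, self._schedule([0.0]))
        assert cycle.incomplete


class TestDailyYield:
    def test_back_computed_yield(self):
        sched = FeedingSchedule(np.array([0.0]), 4.0, 30.0, 1.7)
        assert daily_yield(1430.0, sched) == pytest.approx(1430.0 / 6.8)

    def test_zero_production(self):
        sched = FeedingSchedule(np.array([0.0]), 4.0, 30.0, 1.7)
        assert daily_yield(0.0, sched) == 0.0

    def test_theoretical_maximum_consistency(self):
        from digesterkit.substrate import cod_methane_volume

        sched = FeedingSchedule(np.array([0.0]), 4.0, 30.0, 1.7)
        daily = 6.8 * cod_methane_volume()
        assert daily_yield(daily, sched) == pytest.approx(cod_methane_volume())


class TestGasTimeSeries:
    def test_validation_errors(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _series([0, 0, 1], [1, 1, 1], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="ch4_fraction"):
            _series([0, 1, 2], [1, 1, 1], [0.5, 1.5, 0.5])
        with pytest.raises(ValueError, match="flow"):
            _series([0, 1, 2], [1, -1, 1], [0.5, 0.5, 0.5])

    def test_csv_round_trip(self, tmp_path):
        s = _series([0, 1, 2], [1, 2, 3], [0.5, 0.6, 0.7], temp=21.0, sat=True)
        path = tmp_path / "gas.csv"
        s.to_csv(path)
        back = GasTimeSeries.from_csv(path)
        np.testing.assert_allclose(back.flow, s.flow)
        np.testing.assert_allclose(back.ch4_fraction, s.ch4_fraction)
        assert back.water_saturated.all()

    def test_feed_cod_is_olr_times_hrt(self):
        sched = FeedingSchedule(np.array([0.0]), 4.0, 30.0, 1.7)
        assert sched.feed_cod == pytest.approx(51.0)
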