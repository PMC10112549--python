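"""Cleaning rules, window aggregation, and microstructure metric formulas."""

from datetime import datetime, time, timedelta

import numpy as np
import pytest

from lickometry.errors import ParameterError
from lickometry.microstructure import (
    aggregate_bins,
    clean_minute_bins,
    estimated_ili,
    lick_frequency,
    metric_values,
    phase_percentages,
    summarize_distribution,
)

from conftest import SESSION_START, make_record


class TestCleaning:
    def test_duration_without_licks_is_zeroed(self):
        (r,) = clean_minute_bins([make_record(0, licks=0, lick_duration_ms=250)])
        assert r.lick_duration_ms == 0

    def test_average_over_300ms_is_zeroed(self):
        (r,) = clean_minute_bins([make_record(0, licks=4, lick_duration_ms=1300)])
        assert r.lick_duration_ms == 0

    def test_normal_bin_untouched(self):
        rec = make_record(0, licks=10, lick_duration_ms=510)
        assert clean_minute_bins([rec]) == [rec]

    def test_idempotent_and_licks_never_altered(self):
        records = [
            make_record(0, licks=0, lick_duration_ms=900),
            make_record(1, licks=2, lick_duration_ms=1000),
            make_record(2, licks=7, lick_duration_ms=350),
        ]
        once = clean_minute_bins(records)
        assert clean_minute_bins(once) == once
        assert [r.licks for r in once] == [r.licks for r in records]
        assert all(
            getattr(a, f) == getattr(b, f)
            for a, b in zip(once, records)
            for f in ("bout_count", "bout_duration_ms", "bout_licks")
        )


class TestAggregation:
    def test_hourly_sum_conservation(self, settings):
        records = [make_record(m, licks=10, lick_duration_ms=500) for m in range(60)]
        (agg,) = aggregate_bins(records, "1h", settings)
        assert agg.licks == 600
        assert agg.lick_duration_ms == 30_000
        assert agg.window_start == SESSION_START
        assert agg.window_end == SESSION_START + timedelta(hours=1)

    def test_unknown_width_rejected(self, settings):
        with pytest.raises(ParameterError):
            aggregate_bins([make_record(0)], "5min", settings)

    def test_zero_bout_window_has_undefined_derived_metrics(self, settings):
        records = [make_record(0, licks=12, lick_duration_ms=600)]
        (agg,) = aggregate_bins(records, "1h", settings)
        assert agg.licks == 12
        assert agg.avg_bout_duration_s is None
        assert agg.avg_bout_size is None
        assert agg.lick_frequency_hz is None
        assert agg.est_ili_ms is None

    def test_phase_windows_label_dark_from_lights_off(self, settings):
        # minutes across a full day starting 07:00; dark 19:00-07:00
        records = [make_record(m, licks=1) for m in range(0, 1440, 30)]
        aggs = aggregate_bins(records, "phase", settings)
        for agg in aggs:
            for minute_offset in range(0, 720, 60):
                ts = agg.window_start + timedelta(minutes=minute_offset)
                expected = "dark" if settings.is_dark(ts) else "light"
                assert agg.phase == expected

    def test_reaggregating_hourly_to_daily_matches_direct(self, settings):
        rng = np.random.default_rng(3)
        records = [
            make_record(
                m,
                licks=int(rng.integers(0, 50)),
                lick_duration_ms=int(rng.integers(0, 2000)),
                bout_count=int(rng.integers(0, 3)),
            )
            for m in range(0, 2880, 7)
        ]
        hourly = aggregate_bins(records, "1h", settings)
        # rebuild minute-like records from hourly sums, then 24-h aggregate
        from lickometry.device_log import MinuteRecord

        hourly_as_records = [
            MinuteRecord(
                a.window_start, a.cage, a.side, a.role, a.licks,
                a.lick_duration_ms, a.bout_count, a.bout_duration_ms,
                a.bout_licks, a.bout_lick_duration_ms,
            )
            for a in hourly
        ]
        daily_direct = aggregate_bins(records, "24h", settings)
        daily_re = aggregate_bins(hourly_as_records, "24h", settings)
        assert [
            (a.window_start, a.licks, a.bout_count, a.lick_duration_ms)
            for a in daily_direct
        ] == [
            (a.window_start, a.licks, a.bout_count, a.lick_duration_ms)
            for a in daily_re
        ]


class TestMetricFormulas:
    @pytest.mark.parametrize(
        "licks,duration_s,expected", [(120, 20.0, 6.0), (3, 0.5, 6.0)]
    )
    def test_lick_frequency(self, licks, duration_s, expected):
        assert lick_frequency(licks, duration_s) == pytest.approx(expected)

    def test_lick_frequency_rejects_zero_duration(self):
        with pytest.raises(ParameterError):
            lick_frequency(10, 0.0)

    @pytest.mark.parametrize(
        "dur,contact,licks,expected",
        [(3000, 0, 30, 100.0), (5000, 1530, 30, 115.66666666666667)],
    )
    def test_estimated_ili(self, dur, contact, licks, expected):
        assert estimated_ili(dur, contact, licks) == pytest.approx(expected)

    def test_estimated_ili_rejects_contact_exceeding_duration(self):
        with pytest.raises(ParameterError):
            estimated_ili(1000, 1500, 10)

    def test_constant_gap_bout_gives_exact_ili(self):
        """N licks with constant gap g and duration d: estimated interlick
        interval is (N-1)*g/N exactly, from the bout-duration identity."""
        n, g, d = 25, 110.0, 50.0
        duration = n * d + (n - 1) * g
        assert estimated_ili(duration, n * d, n) == pytest.approx((n - 1) * g / n)

    def test_aggregate_identity_duration_decomposition(self, small_log):
        """bout_duration = bout_lick_duration + bout_licks * est_ili, exactly."""
        cfg, log, _ = small_log
        aggs = aggregate_bins(log.records, "1h", cfg.settings())
        for a in aggs:
            if a.est_ili_ms is None:
                continue
            assert a.bout_duration_ms == pytest.approx(
                a.bout_lick_duration_ms + a.bout_licks * a.est_ili_ms
            )
            assert a.est_ili_ms <= 3000.0


class TestDistributionSummary:
    def test_ili_exclusion_drops_values_over_threshold(self):
        s = summarize_distribution([100, 100, 100, 400], ili_exclusion_ms=300)
        assert s.n == 3
        assert s.mean == pytest.approx(100.0)

    def test_single_value_has_zero_sem_by_convention(self):
        s = summarize_distribution([5.0])
        assert (s.mean, s.median, s.sem) == (5.0, 5.0, 0.0)

    def test_symmetric_values_quartiles_by_linear_interpolation(self):
        s = summarize_distribution(range(1, 10))
        assert (s.mean, s.median) == (5.0, 5.0)
        assert (s.iqr_low, s.iqr_high) == (3.0, 7.0)

    def test_empty_after_exclusion_yields_sentinel(self):
        s = summarize_distribution([400.0, 500.0], ili_exclusion_ms=300)
        assert s.n == 0
        assert np.isnan(s.mean)


class TestPhasePercentages:
    def test_all_dark_licks(self, settings):
        records = [make_record(m, licks=5) for m in range(13 * 60, 14 * 60)]  # 20:00-21:00
        pct = phase_percentages(records, settings)
        assert pct["pct_dark"] == pytest.approx(100.0)

    def test_uniform_day_splits_evenly(self, settings):
        records = [make_record(m, licks=2) for m in range(1440)]
        pct = phase_percentages(records, settings)
        assert pct["pct_dark"] == pytest.approx(50.0)
        assert pct["pct_dark"] + pct["pct_light"] == pytest.approx(100.0)

    def test_no_licks_is_undefined(self, settings):
        assert phase_percentages([make_record(0)], settings) is None
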