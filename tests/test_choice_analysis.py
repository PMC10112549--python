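"""Preference shares, smoothing, volume calibration, and OLS validation."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from lickometry.choice_analysis import (
    CalibrationModel,
    estimate_volume,
    fit_simple_regression,
    period_summary,
    preference_series,
    smooth_series,
)
from lickometry.errors import AlignmentError, ParameterError
from lickometry.microstructure import BinAggregate

from conftest import SESSION_START


def agg(hour: int, side: str, licks: int, **kw) -> BinAggregate:
    start = SESSION_START + timedelta(hours=hour)
    defaults = dict(
        lick_duration_ms=licks * 50, bout_count=0, bout_duration_ms=0,
        bout_licks=0, bout_lick_duration_ms=0,
    )
    defaults.update(kw)
    return BinAggregate(
        start, start + timedelta(hours=1), 1, side,
        "experimental" if side == "right" else "water", licks, **defaults
    )


class TestPreference:
    def test_basic_share(self):
        series = preference_series([agg(0, "right", 300)], [agg(0, "left", 100)])
        assert series.raw_pct[0] == pytest.approx(75.0)

    def test_zero_total_window_is_undefined_not_zero(self):
        series = preference_series([agg(0, "right", 0)], [agg(0, "left", 0)])
        assert np.isnan(series.raw_pct[0])
        assert np.isnan(series.smoothed_pct[0])

    @pytest.mark.parametrize(
        "metric", ["licks", "lick_duration", "bout_count", "bout_duration"]
    )
    def test_equal_metrics_give_fifty_percent(self, metric):
        e = agg(0, "right", 80, bout_count=4, bout_duration_ms=9000, bout_licks=60)
        w = agg(0, "left", 80, bout_count=4, bout_duration_ms=9000, bout_licks=60)
        series = preference_series([e], [w], metric=metric)
        assert series.raw_pct[0] == pytest.approx(50.0)

    def test_misaligned_windows_rejected(self):
        with pytest.raises(AlignmentError):
            preference_series([agg(0, "right", 10)], [agg(1, "left", 10)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 500)),
            min_size=1,
            max_size=24,
        )
    )
    @hyp_settings(max_examples=80, deadline=None, derandomize=True)
    def test_swapping_bottles_mirrors_preference(self, counts):
        exp = [agg(h, "right", e) for h, (e, _) in enumerate(counts)]
        wat = [agg(h, "left", w) for h, (_, w) in enumerate(counts)]
        fwd = preference_series(exp, wat).raw_pct
        rev = preference_series(wat, exp).raw_pct
        defined = ~np.isnan(fwd)
        assert np.allclose(fwd[defined] + rev[defined], 100.0)
        assert np.array_equal(np.isnan(fwd), np.isnan(rev))


class TestSmoothing:
    def test_constant_series_is_fixed_point(self):
        values = [40.0] * 12
        assert np.allclose(smooth_series(values), values)

    def test_impulse_spreads_over_full_windows(self):
        """Window = 3 preceding + current + 2 following: every index whose
        full window contains the impulse at position 3 averages to 1.0."""
        values = [0, 0, 0, 6, 0, 0, 0, 0, 0]
        out = smooth_series(values)
        for i in range(3, 7):  # full windows [i-3, i+2] containing index 3
            assert out[i] == pytest.approx(1.0)
        assert out[7] == pytest.approx(0.0)

    def test_all_undefined_stays_undefined(self):
        out = smooth_series([np.nan] * 5)
        assert np.isnan(out).all()

    def test_undefined_values_are_skipped_not_zeroed(self):
        out = smooth_series([10.0, np.nan, 10.0, 10.0], window_len=3)
        assert np.allclose(out[~np.isnan(out)], 10.0)

    def test_periodic_padding_preserves_mean_exactly(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 100, 24)
        tiled = np.tile(base, 3)
        smoothed = smooth_series(tiled)[24:48]  # interior copy: no edge shrink
        assert smoothed.mean() == pytest.approx(base.mean())


class TestVolume:
    def test_slope_only_inverse(self):
        assert estimate_volume(736.4) == pytest.approx(1.0)
        assert estimate_volume(0.0) == pytest.approx(0.0)
        assert estimate_volume(7364.0) == pytest.approx(10.0)

    def test_linearity_in_licks(self):
        calib = CalibrationModel()
        assert estimate_volume(500, calib) + estimate_volume(700, calib) == pytest.approx(
            estimate_volume(1200, calib)
        )

    def test_full_inverse_inverts_the_line_and_floors_at_zero(self):
        calib = CalibrationModel(mode="full_inverse")
        # licks = 736.4 * 2 - 1172 corresponds to exactly 2 ml
        assert estimate_volume(736.4 * 2 - 1172, calib) == pytest.approx(2.0)
        # the negative intercept maps zero licks to a positive volume —
        # why slope_only is the per-bin default
        assert estimate_volume(0, calib) == pytest.approx(1172 / 736.4)
        positive = CalibrationModel(intercept_licks=500.0, mode="full_inverse")
        assert estimate_volume(0, positive) == 0.0

    def test_default_per_lick_volume_near_1_4_ul(self):
        assert CalibrationModel().ul_per_lick == pytest.approx(1.358, abs=0.001)


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(1.0, 6.0)
        res = fit_simple_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        # Sxx=5, Sxy=3, Syy=5 -> slope 0.6, intercept 1.0, r 0.6
        res = fit_simple_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.slope == pytest.approx(0.6)
        assert res.intercept == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(0.6)
        assert res.r_squared == pytest.approx(res.pearson_r**2)
        assert res.df == (1, 2)
        assert res.slope_ci95[0] <= res.slope <= res.slope_ci95[1]

    def test_anticorrelation(self):
        x = np.arange(10.0)
        res = fit_simple_regression(x, -x)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            fit_simple_regression([1, 2], [1, 2])
        with pytest.raises(ParameterError):
            fit_simple_regression([3, 3, 3], [1, 2, 3])


class TestPeriodSummary:
    def test_empty_period_list_gives_empty_table(self, small_log):
        _, log, _ = small_log
        table = period_summary(log, pd.DataFrame(columns=[
            "start", "end", "cage", "side", "delta_weight_g"]))
        assert table.empty

    def test_period_outside_log_rejected(self, small_log):
        cfg, log, _ = small_log
        periods = pd.DataFrame([
            {"start": cfg.session_start - timedelta(days=2),
             "end": cfg.session_start, "cage": 1, "side": "left",
             "delta_weight_g": 1.0}
        ])
        with pytest.raises(ParameterError):
            period_summary(log, periods)

    def test_tiling_periods_conserve_session_totals(self, small_log):
        cfg, log, _ = small_log
        half = cfg.session_start + timedelta(hours=12)
        end = cfg.session_start + timedelta(days=1)
        rows = []
        for start, stop in [(cfg.session_start, half), (half, end)]:
            for cage in (1, 2):
                for side in ("left", "right"):
                    rows.append({"start": start, "end": stop, "cage": cage,
                                 "side": side, "delta_weight_g": 1.0})
        table = period_summary(log, pd.DataFrame(rows))
        assert table["licks"].sum() == sum(r.licks for r in log.records)
        assert table["bout_count"].sum() == sum(r.bout_count for r in log.records)
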