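"""Two-bottle-choice preference, intake estimation, and weight validation.

Preference for the experimental bottle is the percent share of a chosen
metric (licks, lick duration, bout count, or bout duration) at that bottle
over the two-bottle total, per aligned window.  Preference traces are
smoothed with a length-6 moving average (three preceding windows, the
current one, and two following; shrinking at the edges and skipping
undefined windows).

Licks convert to volume through a linear calibration.  The default slope is
736.4 licks/ml with intercept -1172 licks, i.e. about 1.4 ul per lick; the
slope-only inverse is the per-window default because the negative intercept
is meaningless near zero licks, while the full inverse is offered for whole
recording-period totals.  Bottle-weight changes (1 g = 1 ml) validate the
lick counts through ordinary least squares with an F test on the slope and a
t-based 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .device_log import SessionLog
from .errors import AlignmentError, ParameterError
from .microstructure import BinAggregate

__all__ = [
    "CalibrationModel",
    "RegressionResult",
    "PreferenceSeries",
    "PREFERENCE_METRICS",
    "preference_series",
    "smooth_series",
    "estimate_volume",
    "period_summary",
    "fit_simple_regression",
]

#: Metric name -> BinAggregate counter used for preference shares.
PREFERENCE_METRICS = {
    "licks": "licks",
    "lick_duration": "lick_duration_ms",
    "bout_count": "bout_count",
    "bout_duration": "bout_duration_ms",
}


@dataclass(frozen=True)
class CalibrationModel:
    """Linear licks-to-volume calibration: licks = slope * ml + intercept."""

    slope_licks_per_ml: float = 736.4
    intercept_licks: float = -1172.0
    mode: str = "slope_only"  # or "full_inverse"

    def __post_init__(self):
        if self.slope_licks_per_ml <= 0:
            raise ParameterError("calibration slope must be positive")
        if self.mode not in ("slope_only", "full_inverse"):
            raise ParameterError(f"unknown calibration mode {self.mode!r}")

    @property
    def ul_per_lick(self) -> float:
        return 1000.0 / self.slope_licks_per_ml


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression of y on x with the F test on the slope."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    slope_ci95: tuple[float, float]
    pearson_r: float
    n: int


@dataclass
class PreferenceSeries:
    """Raw and smoothed percent preference per window (NaN = undefined)."""

    windows: list[tuple[datetime, datetime]]
    raw_pct: np.ndarray
    smoothed_pct: np.ndarray
    metric: str = "licks"


def preference_series(
    agg_exp: Sequence[BinAggregate],
    agg_water: Sequence[BinAggregate],
    metric: str = "licks",
    smooth_window: int = 6,
) -> PreferenceSeries:
    """Percent preference for the experimental bottle per aligned window.

    ``raw_pct = 100 * metric_exp / (metric_exp + metric_water)``, undefined
    (NaN) where the two-bottle total is zero.  The two aggregate sequences
    must cover identical windows in the same order.
    """
    if metric not in PREFERENCE_METRICS:
        raise ParameterError(
            f"unknown preference metric {metric!r}; one of {sorted(PREFERENCE_METRICS)}"
        )
    if len(agg_exp) != len(agg_water):
        raise AlignmentError(
            f"window count mismatch: {len(agg_exp)} vs {len(agg_water)}"
        )
    for a, b in zip(agg_exp, agg_water):
        if (a.window_start, a.window_end) != (b.window_start, b.window_end):
            raise AlignmentError(
                f"misaligned windows {a.window_start} vs {b.window_start}"
            )
    attr = PREFERENCE_METRICS[metric]
    e = np.array([getattr(a, attr) for a in agg_exp], dtype=float)
    w = np.array([getattr(a, attr) for a in agg_water], dtype=float)
    total = e + w
    raw = np.full(len(e), np.nan)
    nz = total > 0
    raw[nz] = 100.0 * e[nz] / total[nz]
    return PreferenceSeries(
        windows=[(a.window_start, a.window_end) for a in agg_exp],
        raw_pct=raw,
        smoothed_pct=smooth_series(raw, smooth_window),
        metric=metric,
    )


def smooth_series(values: Sequence[float], window_len: int = 6) -> np.ndarray:
    """Centered moving average, shrinking at the edges, skipping NaNs.

    For the default even length 6 the window spans three preceding values,
    the current one, and two following (offsets -3..+2); odd lengths are
    symmetric.  A window with no defined values stays NaN; constant series
    are fixed points.
    """
    if window_len < 1:
        raise ParameterError("window_len must be >= 1")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    before = window_len // 2
    after = window_len - before - 1
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - before)
        hi = min(n, i + after + 1)
        window = arr[lo:hi]
        defined = window[~np.isnan(window)]
        if defined.size:
            out[i] = defined.mean()
    return out


def estimate_volume(licks: float, calib: CalibrationModel | None = None) -> float:
    """Estimated volume (ml) for a lick count under the calibration model.

    ``slope_only``: licks / slope.  ``full_inverse``: inverts the full line
    (licks - intercept) / slope, floored at zero; sensible only for
    whole-period totals.
    """
    if calib is None:
        calib = CalibrationModel()
    if licks < 0:
        raise ParameterError("licks must be non-negative")
    if calib.mode == "slope_only":
        return licks / calib.slope_licks_per_ml
    return max(0.0, (licks - calib.intercept_licks) / calib.slope_licks_per_ml)


def period_summary(
    log: SessionLog,
    periods: pd.DataFrame,
    calib: CalibrationModel | None = None,
) -> pd.DataFrame:
    """Per-period, per-bottle totals with preference by every metric.

    ``periods`` has columns ``start, end, cage, side, delta_weight_g`` (one
    row per bottle per period; half-open periods; weight change as positive
    grams consumed, 1 g = 1 ml).  The output adds per-bottle counter totals,
    estimated volume, and this bottle's percent share of each metric and of
    the weight change within its cage and period.

    Raises :class:`ParameterError` when a period lies outside the log span.
    """
    if calib is None:
        calib = CalibrationModel()
    if periods.empty:
        return pd.DataFrame(
            columns=[
                "start", "end", "cage", "side", "role",
                *["licks", "lick_duration_ms", "bout_count", "bout_duration_ms",
                  "bout_licks", "bout_lick_duration_ms"],
                "est_volume_ml", "delta_weight_ml",
                *[f"pref_{m}" for m in PREFERENCE_METRICS], "pref_weight",
            ]
        )
    periods = periods.copy()
    periods["start"] = pd.to_datetime(periods["start"])
    periods["end"] = pd.to_datetime(periods["end"])

    if log.records:
        log_start = min(r.timestamp for r in log.records)
        log_end = max(r.timestamp for r in log.records)
    else:
        raise ParameterError("log has no records")
    bin_delta = pd.Timedelta(seconds=log.settings.bin_size_s)
    if (periods["start"] < pd.Timestamp(log_start)).any() or (
        periods["end"] > pd.Timestamp(log_end) + bin_delta
    ).any():
        raise ParameterError("a period lies outside the span of the log")

    from .device_log import records_to_frame

    df = records_to_frame(log.records)
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    rows = []
    counter_cols = [
        "licks", "lick_duration_ms", "bout_count", "bout_duration_ms",
        "bout_licks", "bout_lick_duration_ms",
    ]
    for _, p in periods.iterrows():
        mask = (
            (df["timestamp"] >= p["start"])
            & (df["timestamp"] < p["end"])
            & (df["cage"] == p["cage"])
            & (df["side"] == p["side"])
        )
        sub = df[mask]
        sums = {c: int(sub[c].sum()) for c in counter_cols}
        rows.append(
            {
                "start": p["start"],
                "end": p["end"],
                "cage": int(p["cage"]),
                "side": p["side"],
                "role": log.settings.role_of(int(p["cage"]), p["side"]),
                **sums,
                "est_volume_ml": estimate_volume(sums["licks"], calib),
                "delta_weight_ml": float(p["delta_weight_g"]),
            }
        )
    out = pd.DataFrame(rows)

    # per-bottle share of the cage total, per metric and by weight
    for metric, col in PREFERENCE_METRICS.items():
        out[f"pref_{metric}"] = np.nan
    out["pref_weight"] = np.nan
    for (_, _, cage), group in out.groupby(["start", "end", "cage"]):
        if len(group) != 2:
            continue  # share undefined without both bottles
        i, j = group.index
        for metric, col in PREFERENCE_METRICS.items():
            total = out.loc[i, col] + out.loc[j, col]
            if total > 0:
                out.loc[i, f"pref_{metric}"] = 100.0 * out.loc[i, col] / total
                out.loc[j, f"pref_{metric}"] = 100.0 * out.loc[j, col] / total
        wtotal = out.loc[i, "delta_weight_ml"] + out.loc[j, "delta_weight_ml"]
        if wtotal > 0:
            out.loc[i, "pref_weight"] = 100.0 * out.loc[i, "delta_weight_ml"] / wtotal
            out.loc[j, "pref_weight"] = 100.0 * out.loc[j, "delta_weight_ml"] / wtotal
    return out


def fit_simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with slope F test and 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise ParameterError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("values must be finite")
    if np.ptp(x) == 0:
        raise ParameterError("x has zero variance")

    fit = stats.linregress(x, y)
    dfd = n - 2
    if fit.stderr > 0:
        f_stat = (fit.slope / fit.stderr) ** 2
    else:
        f_stat = math.inf
    tcrit = stats.t.ppf(0.975, dfd)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        f_statistic=float(f_stat),
        df=(1, dfd),
        slope_ci95=(float(ci[0]), float(ci[1])),
        pearson_r=float(fit.rvalue),
        n=n,
    )
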