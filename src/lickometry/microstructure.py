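"""Cleaning, binning, and drinking-microstructure metrics.

The device occasionally suffers stuck-sensor artifacts: a touch sensor fails
to register release until the next touch, inflating recorded contact time
without adding licks.  :func:`clean_minute_bins` zeroes the lick-duration
counter of any minute bin that shows contact time without licks, or an
average contact time per lick above 300 ms (an order of magnitude beyond a
physiological lick).

Minute counters are then summed into 1-h, 24-h, or 12-h light/dark-phase
windows and four microstructure metrics are derived per window:

- average bout duration (s)   = bout_duration / bout_count
- average bout size (licks)   = bout_licks / bout_count
- lick frequency (Hz)         = bout_licks / bout_duration_s
- estimated interlick interval (ms)
                              = (bout_duration - bout_lick_duration) / bout_licks

The estimated interlick interval is the mean silence between the offset of
one lick and the onset of the next within bouts; the identity
``bout_duration = bout_lick_duration + bout_licks * est_ili`` holds exactly
by construction.  Any derived metric is undefined (``None``) when its
denominator is zero.  Distribution summaries of per-bin values optionally
drop interlick intervals above 300 ms, which flag residual sensor artifacts
rather than drinking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .device_log import DeviceSettings, MinuteRecord, records_to_frame
from .errors import ParameterError

__all__ = [
    "BinAggregate",
    "DistributionSummary",
    "clean_minute_bins",
    "aggregate_bins",
    "aggregates_to_frame",
    "metric_values",
    "lick_frequency",
    "estimated_ili",
    "summarize_distribution",
    "phase_percentages",
    "ILI_EXCLUSION_MS",
    "MAX_AVG_LICK_DURATION_MS",
]

#: Default per-lick average contact time above which a bin's lick duration is
#: treated as a stuck-sensor artifact and zeroed.
MAX_AVG_LICK_DURATION_MS = 300.0
#: Default bin-level estimated-interlick-interval exclusion threshold.
ILI_EXCLUSION_MS = 300.0

_SUM_FIELDS = (
    "licks",
    "lick_duration_ms",
    "bout_count",
    "bout_duration_ms",
    "bout_licks",
    "bout_lick_duration_ms",
)


@dataclass(frozen=True)
class BinAggregate:
    """Counter sums over one half-open window for one channel, plus derived
    microstructure metrics (``None`` where the denominator is zero)."""

    window_start: datetime
    window_end: datetime
    cage: int
    side: str
    role: str
    licks: int
    lick_duration_ms: int
    bout_count: int
    bout_duration_ms: int
    bout_licks: int
    bout_lick_duration_ms: int
    phase: str | None = None  # "dark"/"light" for phase windows

    @property
    def avg_bout_duration_s(self) -> float | None:
        if self.bout_count == 0:
            return None
        return self.bout_duration_ms / 1000.0 / self.bout_count

    @property
    def avg_bout_size(self) -> float | None:
        if self.bout_count == 0:
            return None
        return self.bout_licks / self.bout_count

    @property
    def lick_frequency_hz(self) -> float | None:
        if self.bout_duration_ms == 0:
            return None
        return lick_frequency(self.bout_licks, self.bout_duration_ms / 1000.0)

    @property
    def est_ili_ms(self) -> float | None:
        if self.bout_licks == 0:
            return None
        return estimated_ili(
            self.bout_duration_ms, self.bout_lick_duration_ms, self.bout_licks
        )


@dataclass(frozen=True)
class DistributionSummary:
    """Location/scale summary of per-bin metric values after exclusions."""

    n: int
    mean: float
    sem: float
    median: float
    iqr_low: float
    iqr_high: float


def clean_minute_bins(
    records: Sequence[MinuteRecord],
    max_avg_lick_duration_ms: float = MAX_AVG_LICK_DURATION_MS,
) -> list[MinuteRecord]:
    """Zero artifact-inflated lick durations; all other fields untouched.

    A bin is flagged when it has contact time but no licks, or when its
    average contact time per lick exceeds ``max_avg_lick_duration_ms``.
    Idempotent; never alters lick counts.
    """
    out: list[MinuteRecord] = []
    for r in records:
        bad = (r.licks == 0 and r.lick_duration_ms > 0) or (
            r.licks > 0 and r.lick_duration_ms / r.licks > max_avg_lick_duration_ms
        )
        out.append(replace(r, lick_duration_ms=0) if bad else r)
    return out


def _phase_window(ts: datetime, settings: DeviceSettings) -> tuple[datetime, datetime, str]:
    """The 12-h light/dark window containing ``ts`` and its phase label."""
    day = ts.date()
    off, on = settings.lights_off, settings.lights_on
    if settings.is_dark(ts):
        if off > on:  # dark wraps midnight
            if ts.time() >= off:
                start = datetime.combine(day, off)
            else:
                start = datetime.combine(day - timedelta(days=1), off)
            end = datetime.combine(start.date() + timedelta(days=1), on)
        else:
            start = datetime.combine(day, off)
            end = datetime.combine(day, on)
        return start, end, "dark"
    # light phase
    if off > on:  # light runs lights_on..lights_off within one date
        start = datetime.combine(day, on)
        end = datetime.combine(day, off)
    else:  # light wraps midnight

        if ts.time() >= on:
            start = datetime.combine(day, on)
            end = datetime.combine(day + timedelta(days=1), off)
        else:
            start = datetime.combine(day - timedelta(days=1), on)
            end = datetime.combine(day, off)
    return start, end, "light"


def aggregate_bins(
    records: Sequence[MinuteRecord],
    width: str,
    settings: DeviceSettings,
) -> list[BinAggregate]:
    """Sum minute records into windows per channel.

    ``width`` is ``"1h"`` (clock-hour windows), ``"24h"`` (day windows
    anchored to the clock hour of the earliest record), or ``"phase"``
    (12-h light/dark windows from the settings schedule).  Windows are
    half-open and only windows containing records are emitted.
    """
    if width not in ("1h", "24h", "phase"):
        raise ParameterError(f"unknown bin width {width!r}; use '1h', '24h' or 'phase'")
    if not records:
        return []

    df = records_to_frame(records)
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    if width == "1h":
        ws = df["timestamp"].dt.floor("h")
        df["window_start"] = ws
        df["window_end"] = ws + pd.Timedelta(hours=1)
        df["phase"] = None
    elif width == "24h":
        anchor = df["timestamp"].min().floor("h")
        idx = ((df["timestamp"] - anchor) // pd.Timedelta(hours=24)).astype(int)
        df["window_start"] = anchor + idx * pd.Timedelta(hours=24)
        df["window_end"] = df["window_start"] + pd.Timedelta(hours=24)
        df["phase"] = None
    else:
        wins = [
            _phase_window(ts.to_pydatetime(), settings) for ts in df["timestamp"]
        ]
        df["window_start"] = [w[0] for w in wins]
        df["window_end"] = [w[1] for w in wins]
        df["phase"] = [w[2] for w in wins]

    grouped = df.groupby(
        ["cage", "side", "window_start", "window_end"], sort=True, dropna=False
    )
    aggs: list[BinAggregate] = []
    for (cage, side, wstart, wend), g in grouped:
        aggs.append(
            BinAggregate(
                window_start=wstart.to_pydatetime(),
                window_end=wend if isinstance(wend, datetime) else wend.to_pydatetime(),
                cage=int(cage),
                side=side,
                role=g["role"].iloc[0],
                phase=g["phase"].iloc[0],
                **{f: int(g[f].sum()) for f in _SUM_FIELDS},
            )
        )
    aggs.sort(key=lambda a: (a.window_start, a.cage, a.side))
    return aggs


_DERIVED = ("avg_bout_duration_s", "avg_bout_size", "lick_frequency_hz", "est_ili_ms")


def aggregates_to_frame(aggs: Iterable[BinAggregate]) -> pd.DataFrame:
    """Tidy export of aggregates: sums plus derived metrics (NaN = undefined)."""
    aggs = list(aggs)
    data = {
        "window_start": [a.window_start for a in aggs],
        "window_end": [a.window_end for a in aggs],
        "cage": [a.cage for a in aggs],
        "side": [a.side for a in aggs],
        "role": [a.role for a in aggs],
        "phase": [a.phase for a in aggs],
        **{f: [getattr(a, f) for a in aggs] for f in _SUM_FIELDS},
    }
    for name in _DERIVED:
        data[name] = [
            np.nan if getattr(a, name) is None else getattr(a, name) for a in aggs
        ]
    return pd.DataFrame(data)


def metric_values(aggs: Iterable[BinAggregate], metric: str) -> np.ndarray:
    """Defined per-bin values of one derived metric, as a float array."""
    if metric not in _DERIVED:
        raise ParameterError(f"unknown metric {metric!r}; one of {_DERIVED}")
    vals = [getattr(a, metric) for a in aggs]
    return np.array([v for v in vals if v is not None], dtype=float)


def lick_frequency(bout_licks: float, bout_duration_s: float) -> float:
    """Licks per second during bouts: ``bout_licks / bout_duration_s``."""
    if bout_duration_s <= 0:
        raise ParameterError("bout_duration_s must be positive")
    return bout_licks / bout_duration_s


def estimated_ili(
    bout_duration_ms: float, bout_lick_duration_ms: float, bout_licks: float
) -> float:
    """Mean within-bout silence between licks, in milliseconds.

    ``(bout_duration_ms - bout_lick_duration_ms) / bout_licks``; the
    numerator is the total non-contact time inside bouts.
    """
    if bout_licks <= 0:
        raise ParameterError("bout_licks must be positive")
    if bout_lick_duration_ms > bout_duration_ms:
        raise ParameterError(
            "bout_lick_duration_ms cannot exceed bout_duration_ms"
        )
    return (bout_duration_ms - bout_lick_duration_ms) / bout_licks


def summarize_distribution(
    values: Iterable[float],
    ili_exclusion_ms: float | None = None,
) -> DistributionSummary:
    """Summarize per-bin metric values: n, mean, SEM, median, IQR.

    Pass ``ili_exclusion_ms`` (conventionally 300) when summarizing estimated
    interlick intervals to drop artifact-range values before summarizing.
    NaNs are ignored.  A single value has SEM 0 by convention; an empty input
    (or one emptied by the exclusion) yields the ``n=0`` sentinel with NaN
    statistics.

    Quantiles (median and quartiles) use linear interpolation between closest
    ranks, the numpy default.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if ili_exclusion_ms is not None:
        arr = arr[arr <= ili_exclusion_ms]
    n = int(arr.size)
    if n == 0:
        nan = float("nan")
        return DistributionSummary(0, nan, nan, nan, nan, nan)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q25, q50, q75 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return DistributionSummary(n, mean, sem, q50, q25, q75)


def phase_percentages(
    records: Sequence[MinuteRecord],
    settings: DeviceSettings,
    period: tuple[datetime, datetime] | None = None,
) -> dict[str, float] | None:
    """Percent of total licks in the dark vs light phase over ``period``.

    Returns ``{"pct_dark": ..., "pct_light": ...}`` summing to 100, or
    ``None`` when the period contains no licks.
    """
    dark = 0
    total = 0
    for r in records:
        if period is not None and not (period[0] <= r.timestamp < period[1]):
            continue
        total += r.licks
        if settings.is_dark(r.timestamp):
            dark += r.licks
    if total == 0:
        return None
    pct_dark = 100.0 * dark / total
    return {"pct_dark": pct_dark, "pct_light": 100.0 - pct_dark}
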