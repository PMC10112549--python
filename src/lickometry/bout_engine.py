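"""Drinking-bout detection from raw lick-event streams, and minute binning.

A lick is one tongue-contact interval on a sipper.  A drinking bout begins
when three licks occur within less than one second (onset-to-onset span of
the qualifying triplet strictly below ``start_window_ms``) and ends once no
lick follows within three seconds (offset-to-next-onset gap strictly above
``end_gap_ms``).  The three-second silence that closes a bout is deadtime and
is excluded from the reported bout duration, so a bout's duration runs from
its first lick's onset to its last lick's offset.  Boundary ties follow the
strict readings: a triplet spanning exactly 1.000 s does not start a bout and
a gap of exactly 3.000 s does not end one.

Licks that precede the qualifying triplet are never pulled into the bout,
even when they fall within three seconds of it: the bout starts at the first
lick of the first qualifying triplet.  A bout still open when the stream ends
is finalized at its last lick's offset without waiting out the deadtime.

:func:`brute_force_bouts` re-derives the same segmentation by exhaustive
scanning and serves as the independent oracle for :func:`detect_bouts` in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np

from .device_log import DeviceSettings, MinuteRecord, SessionLog, SessionMarker
from .errors import IntegrityError, ParameterError

__all__ = [
    "LickEvent",
    "Bout",
    "detect_bouts",
    "brute_force_bouts",
    "bin_events",
    "split_by_channel",
    "events_to_log",
]


@dataclass(frozen=True)
class LickEvent:
    """One tongue-contact interval on one channel.

    ``onset_ms`` is measured from the session start; ``duration_ms`` is the
    actual contact time on the sipper.
    """

    cage: int
    side: str
    onset_ms: float
    duration_ms: float

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms

    @property
    def channel(self) -> tuple[int, str]:
        return (self.cage, self.side)


@dataclass(frozen=True)
class Bout:
    """A detected cluster of at least three licks on one channel.

    ``duration_ms`` (offset minus onset) already excludes the trailing 3-s
    deadtime used to close the bout.
    """

    cage: int
    side: str
    onset_ms: float
    offset_ms: float
    length: int
    lick_duration_total_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def channel(self) -> tuple[int, str]:
        return (self.cage, self.side)


def split_by_channel(events: Iterable[LickEvent]) -> dict[tuple[int, str], list[LickEvent]]:
    """Group a mixed stream by (cage, side), preserving order."""
    out: dict[tuple[int, str], list[LickEvent]] = {}
    for e in events:
        out.setdefault(e.channel, []).append(e)
    return out


def _check_stream(events: Sequence[LickEvent]) -> tuple[int, str]:
    """Validate single-channel ordering/overlap invariants; return the channel."""
    if not events:
        raise ParameterError("empty stream has no channel")
    channel = events[0].channel
    prev_offset = -math.inf
    for i, e in enumerate(events):
        if e.channel != channel:
            raise ParameterError(
                f"detect_bouts expects a single channel; got {channel} and {e.channel}"
            )
        if e.duration_ms <= 0:
            raise ParameterError(f"event {i}: non-positive duration {e.duration_ms}")
        if e.onset_ms < prev_offset:
            raise ParameterError(
                f"event {i}: onset {e.onset_ms} overlaps previous offset {prev_offset}"
            )
        prev_offset = e.offset_ms
    return channel


def detect_bouts(
    events: Sequence[LickEvent],
    start_licks: int = 3,
    start_window_ms: float = 1000.0,
    end_gap_ms: float = 3000.0,
) -> list[Bout]:
    """Segment one channel's lick stream into drinking bouts.

    Single forward pass: slide a candidate window of ``start_licks`` licks
    until its onset span is strictly below ``start_window_ms`` (with every
    internal gap within ``end_gap_ms``), then extend the bout lick by lick
    while each offset-to-next-onset gap stays within ``end_gap_ms``.

    Returns disjoint, ordered bouts; every lick belongs to at most one bout.
    """
    if not events:
        return []
    if start_licks < 2:
        raise ParameterError("start_licks must be at least 2")
    cage, side = _check_stream(events)

    onsets = np.array([e.onset_ms for e in events], dtype=float)
    durations = np.array([e.duration_ms for e in events], dtype=float)
    offsets = onsets + durations
    n = len(events)
    k = start_licks

    bouts: list[Bout] = []
    i = 0
    while i + k <= n:
        if onsets[i + k - 1] - onsets[i] < start_window_ms and all(
            onsets[j + 1] - offsets[j] <= end_gap_ms for j in range(i, i + k - 1)
        ):
            j = i + k - 1
            while j + 1 < n and onsets[j + 1] - offsets[j] <= end_gap_ms:
                j += 1
            bouts.append(
                Bout(
                    cage,
                    side,
                    float(onsets[i]),
                    float(offsets[j]),
                    j - i + 1,
                    # left-to-right sum: bit-identical to per-event accumulation
                    float(sum(durations[i : j + 1], 0.0)),
                )
            )
            i = j + 1
        else:
            i += 1
    return bouts


def brute_force_bouts(
    events: Sequence[LickEvent],
    start_licks: int = 3,
    start_window_ms: float = 1000.0,
    end_gap_ms: float = 3000.0,
) -> list[Bout]:
    """Reference segmentation by exhaustive scan (test oracle; small inputs).

    Walks every candidate start index in order, re-testing the bout-start
    definition from scratch on the raw event list and claiming member licks
    greedily until the first silence longer than ``end_gap_ms``.  Kept free
    of numpy and of any code shared with :func:`detect_bouts` so the two can
    disagree if either is wrong.
    """
    if not events:
        return []
    cage, side = _check_stream(events)
    n = len(events)
    claimed = [False] * n
    bouts: list[Bout] = []
    t = 0
    while t + start_licks <= n:
        if claimed[t]:
            t += 1
            continue
        window = events[t : t + start_licks]
        span_ok = window[-1].onset_ms - window[0].onset_ms < start_window_ms
        gaps_ok = all(
            window[u + 1].onset_ms - window[u].offset_ms <= end_gap_ms
            for u in range(start_licks - 1)
        )
        if span_ok and gaps_ok:
            members = list(range(t, t + start_licks))
            last = members[-1]
            for u in range(last + 1, n):
                if events[u].onset_ms - events[last].offset_ms <= end_gap_ms:
                    members.append(u)
                    last = u
                else:
                    break
            for m in members:
                claimed[m] = True
            bouts.append(
                Bout(
                    cage,
                    side,
                    events[members[0]].onset_ms,
                    events[members[-1]].offset_ms,
                    len(members),
                    sum(events[m].duration_ms for m in members),
                )
            )
            t = last + 1
        else:
            t += 1
    return bouts


def bin_events(
    events: Sequence[LickEvent],
    bouts: Sequence[Bout],
    settings: DeviceSettings,
    session_start: datetime,
    n_bins: int | None = None,
    channels: Sequence[tuple[int, str]] | None = None,
) -> list[MinuteRecord]:
    """Accumulate events and bouts into per-bin counters, as the device would.

    ``channels`` may list (cage, side) pairs to emit records for (zero-filled
    where silent); by default only channels present in ``events`` appear.

    Each lick is credited to the bin containing its onset; each whole bout's
    counters are credited to the bin containing its last lick's offset (an
    online recorder can only book a bout once it has closed).  Every elapsed
    bin gets a record for every channel seen in ``events``, zero-filled where
    nothing happened.  Durations are rounded to integer milliseconds.

    Raises :class:`IntegrityError` when the bouts cannot have been derived
    from the events (per-channel bout totals exceeding event totals).
    """
    bin_ms = settings.bin_size_s * 1000.0
    by_chan = split_by_channel(events)
    bouts_by_chan: dict[tuple[int, str], list[Bout]] = {}
    for b in bouts:
        bouts_by_chan.setdefault(b.channel, []).append(b)
    unknown = set(bouts_by_chan) - set(by_chan)
    if unknown:
        raise IntegrityError(f"bouts reference channels with no events: {sorted(unknown)}")

    if n_bins is None:
        horizon = 0.0
        for evs in by_chan.values():
            horizon = max(horizon, max(e.onset_ms for e in evs))
        for bs in bouts_by_chan.values():
            horizon = max(horizon, max(b.offset_ms for b in bs))
        n_bins = int(horizon // bin_ms) + 1

    all_channels = set(by_chan)
    if channels is not None:
        all_channels |= {tuple(c) for c in channels}

    records: list[MinuteRecord] = []
    for chan in sorted(all_channels):
        cage, side = chan
        evs = by_chan.get(chan, [])
        bts = bouts_by_chan.get(chan, [])

        lick_total = sum(e.duration_ms for e in evs)
        bout_lick_total = sum(b.lick_duration_total_ms for b in bts)
        if sum(b.length for b in bts) > len(evs) or bout_lick_total > lick_total + 1e-6:
            raise IntegrityError(
                f"channel {chan}: bout totals exceed event totals; bouts were "
                "not derived from these events"
            )

        licks = np.zeros(n_bins, dtype=np.int64)
        lick_dur = np.zeros(n_bins, dtype=float)
        bout_count = np.zeros(n_bins, dtype=np.int64)
        bout_dur = np.zeros(n_bins, dtype=float)
        bout_licks = np.zeros(n_bins, dtype=np.int64)
        bout_lick_dur = np.zeros(n_bins, dtype=float)

        onsets = np.array([e.onset_ms for e in evs])
        durs = np.array([e.duration_ms for e in evs])
        idx = (onsets // bin_ms).astype(np.int64)
        if (idx < 0).any() or (idx >= n_bins).any():
            raise ParameterError("event outside the binned session span")
        np.add.at(licks, idx, 1)
        np.add.at(lick_dur, idx, durs)

        for b in bts:
            bi = int(b.offset_ms // bin_ms)
            if bi >= n_bins or bi < 0:
                raise ParameterError("bout closes outside the binned session span")
            bout_count[bi] += 1
            bout_dur[bi] += b.duration_ms
            bout_licks[bi] += b.length
            bout_lick_dur[bi] += b.lick_duration_total_ms

        role = settings.role_of(cage, side)
        for bi in range(n_bins):
            ts = session_start + timedelta(milliseconds=bi * bin_ms)
            records.append(
                MinuteRecord(
                    ts,
                    cage,
                    side,
                    role,
                    int(licks[bi]),
                    int(round(lick_dur[bi])),
                    int(bout_count[bi]),
                    int(round(bout_dur[bi])),
                    int(bout_licks[bi]),
                    int(round(bout_lick_dur[bi])),
                )
            )
    records.sort(key=lambda r: (r.timestamp, r.cage, r.side))
    return records


def events_to_log(
    events: Sequence[LickEvent],
    settings: DeviceSettings,
    session_start: datetime,
    n_bins: int | None = None,
    **detect_kwargs,
) -> tuple[SessionLog, list[Bout]]:
    """Full device emulation: detect bouts per channel, bin, assemble a log."""
    all_bouts: list[Bout] = []
    for chan, evs in sorted(split_by_channel(events).items()):
        all_bouts.extend(detect_bouts(evs, **detect_kwargs))
    records = bin_events(events, all_bouts, settings, session_start, n_bins=n_bins)
    log = SessionLog(
        settings=settings,
        records=records,
        markers=[SessionMarker(session_start, "START")],
    )
    return log, all_bouts
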