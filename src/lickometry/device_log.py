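"""Minute-binned lickometer session logs: read, write, validate.

A session log is the interchange format between the recording device (or the
simulator standing in for it) and the analysis modules.  One file holds a
settings header, one data row per (cage, side, minute) with the per-bin
counters the device accumulates, and marker rows for session events such as
pauses or sensor timeouts.

Dialect
-------
UTF-8, comma-separated, LF line endings.  The file opens with a block of
``#settings key=value`` lines (``bin_size_s``, ``lights_off``, ``lights_on``
and, when any bottle holds an experimental solution,
``experimental_side=<cage>:<side>,...``), followed by the fixed column header

    rowtype,timestamp,cage,side,role,licks,lick_duration_ms,bout_count,
    bout_duration_ms,bout_licks,bout_lick_duration_ms

Data rows carry ``rowtype=DATA``.  Marker rows carry the marker kind as
``rowtype`` with all counter columns empty and any free-text note in the
``role`` column.  Marker kinds outside the known set are preserved on read as
``UNKNOWN`` markers whose note records the original text.  Timestamps are
ISO 8601 local time at minute precision.  Bins are half-open ``[t, t+bin)``;
a lick is counted in the bin containing its onset.  Bins elapsed while the
recording was paused are absent rather than zero-filled, because the device
records nothing while paused.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "MinuteRecord",
    "SessionMarker",
    "DeviceSettings",
    "SessionLog",
    "Finding",
    "MARKER_KINDS",
    "read_log",
    "write_log",
    "validate_log",
    "records_to_frame",
    "frame_to_records",
]

SIDES = ("left", "right")
ROLES = ("water", "experimental")
#: Marker kinds the device itself can write.
MARKER_KINDS = (
    "START",
    "PAUSE",
    "RESUME",
    "TIMEOUT",
    "SD_FAIL",
    "SIDE_SWAP",
    "SOLUTION_CHANGE",
)
UNKNOWN_MARKER = "UNKNOWN"

_COLUMNS = (
    "rowtype,timestamp,cage,side,role,licks,lick_duration_ms,bout_count,"
    "bout_duration_ms,bout_licks,bout_lick_duration_ms"
)
_TS_FMT = "%Y-%m-%dT%H:%M"
_COUNTER_FIELDS = (
    "licks",
    "lick_duration_ms",
    "bout_count",
    "bout_duration_ms",
    "bout_licks",
    "bout_lick_duration_ms",
)


@dataclass(frozen=True)
class MinuteRecord:
    """Per-channel counters for one device bin (one minute by default).

    ``licks``/``lick_duration_ms`` count every sipper contact in the bin;
    the ``bout_*`` counters cover only licks inside detected bouts, credited
    to the bin in which the bout closed.
    """

    timestamp: datetime
    cage: int
    side: str
    role: str
    licks: int = 0
    lick_duration_ms: int = 0
    bout_count: int = 0
    bout_duration_ms: int = 0
    bout_licks: int = 0
    bout_lick_duration_ms: int = 0

    @property
    def channel(self) -> tuple[int, str]:
        return (self.cage, self.side)


@dataclass(frozen=True)
class SessionMarker:
    """A non-data line in the log (session start, pause, sensor timeout...)."""

    timestamp: datetime
    kind: str
    note: str = ""


@dataclass
class DeviceSettings:
    """Recording configuration stored in the log header.

    ``lights_off``/``lights_on`` define the dark phase, which may wrap
    midnight (e.g. 19:00 -> 07:00).  ``experimental_side_by_cage`` maps a cage
    to the side holding the experimental solution; cages absent from the map
    have water in both bottles.
    """

    bin_size_s: int = 60
    lights_off: time = time(19, 0)
    lights_on: time = time(7, 0)
    experimental_side_by_cage: dict[int, str] = field(default_factory=dict)

    def role_of(self, cage: int, side: str) -> str:
        return (
            "experimental"
            if self.experimental_side_by_cage.get(cage) == side
            else "water"
        )

    def is_dark(self, when: datetime | time) -> bool:
        """True if the clock time falls in the lights-off (dark/active) phase."""
        t = when.time() if isinstance(when, datetime) else when
        off, on = self.lights_off, self.lights_on
        if off > on:  # dark phase wraps midnight
            return t >= off or t < on
        return off <= t < on


@dataclass
class SessionLog:
    """A full recording: settings, minute records, and session markers."""

    settings: DeviceSettings
    records: list[MinuteRecord] = field(default_factory=list)
    markers: list[SessionMarker] = field(default_factory=list)

    def channels(self) -> list[tuple[int, str]]:
        return sorted({r.channel for r in self.records})


@dataclass(frozen=True)
class Finding:
    """One coded problem reported by :func:`validate_log`."""

    code: str
    timestamp: datetime | None
    cage: int | None = None
    side: str | None = None
    message: str = ""


def _fmt_ts(ts: datetime) -> str:
    return ts.strftime(_TS_FMT)


def _settings_lines(settings: DeviceSettings) -> list[str]:
    lines = [
        f"#settings bin_size_s={settings.bin_size_s}",
        f"#settings lights_off={settings.lights_off.strftime('%H:%M')}",
        f"#settings lights_on={settings.lights_on.strftime('%H:%M')}",
    ]
    if settings.experimental_side_by_cage:
        pairs = ",".join(
            f"{cage}:{side}"
            for cage, side in sorted(settings.experimental_side_by_cage.items())
        )
        lines.append(f"#settings experimental_side={pairs}")
    return lines


def write_log(log: SessionLog, path) -> None:
    """Serialize ``log`` to ``path`` in the canonical dialect.

    Output is byte-identical across runs for equal inputs: settings lines in
    fixed order, rows merged by timestamp with markers preceding data rows at
    the same minute, data rows in (timestamp, cage, side) order.
    """
    buf = io.StringIO()
    for line in _settings_lines(log.settings):
        buf.write(line + "\n")
    buf.write(_COLUMNS + "\n")
    writer = csv.writer(buf, lineterminator="\n")

    rows: list[tuple] = []
    for m in log.markers:
        rows.append(((m.timestamp, 0, -1, ""), [m.kind, _fmt_ts(m.timestamp), "", "",
                                                m.note, "", "", "", "", "", ""]))
    for r in log.records:
        rows.append(
            (
                (r.timestamp, 1, r.cage, r.side),
                [
                    "DATA",
                    _fmt_ts(r.timestamp),
                    str(r.cage),
                    r.side,
                    r.role,
                    str(r.licks),
                    str(r.lick_duration_ms),
                    str(r.bout_count),
                    str(r.bout_duration_ms),
                    str(r.bout_licks),
                    str(r.bout_lick_duration_ms),
                ],
            )
        )
    rows.sort(key=lambda kv: kv[0])
    for _, row in rows:
        writer.writerow(row)

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def _parse_settings(lines: list[str]) -> DeviceSettings:
    settings = DeviceSettings()
    for line in lines:
        body = line[len("#settings "):].strip()
        if "=" not in body:
            raise FormatError(f"malformed settings line: {line!r}")
        key, value = body.split("=", 1)
        if key == "bin_size_s":
            settings.bin_size_s = int(value)
        elif key in ("lights_off", "lights_on"):
            hh, mm = value.split(":")
            setattr(settings, key, time(int(hh), int(mm)))
        elif key == "experimental_side":
            mapping: dict[int, str] = {}
            if value:
                for pair in value.split(","):
                    cage, side = pair.split(":")
                    mapping[int(cage)] = side
            settings.experimental_side_by_cage = mapping
        # unknown settings keys are ignored (forward compatibility)
    return settings


def read_log(path) -> SessionLog:
    """Parse a session log, enforcing the type invariants.

    Raises
    ------
    FormatError
        Missing settings header or column header, unparseable field.
    IntegrityError
        Negative counter or non-monotone timestamps within a channel series,
        reported with the offending line number.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        raw_lines = fh.read().split("\n")
    if raw_lines and raw_lines[-1] == "":
        raw_lines.pop()

    settings_lines = []
    i = 0
    while i < len(raw_lines) and raw_lines[i].startswith("#"):
        if raw_lines[i].startswith("#settings "):
            settings_lines.append(raw_lines[i])
        i += 1
    if not settings_lines:
        raise FormatError("file does not begin with a #settings header block")
    settings = _parse_settings(settings_lines)

    if i >= len(raw_lines) or raw_lines[i] != _COLUMNS:
        raise FormatError(
            f"line {i + 1}: expected column header {_COLUMNS!r}"
        )
    header_line = i

    records: list[MinuteRecord] = []
    markers: list[SessionMarker] = []
    last_ts: dict[tuple[int, str], datetime] = {}
    reader = csv.reader(raw_lines[header_line + 1:])
    for offset, row in enumerate(reader):
        lineno = header_line + 2 + offset
        if not row or (len(row) == 1 and not row[0]):
            continue
        if len(row) != 11:
            raise FormatError(f"line {lineno}: expected 11 fields, got {len(row)}")
        rowtype = row[0]
        try:
            ts = datetime.strptime(row[1], _TS_FMT)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad timestamp {row[1]!r}") from exc

        if rowtype != "DATA":
            note = row[4]
            if rowtype in MARKER_KINDS:
                markers.append(SessionMarker(ts, rowtype, note))
            else:
                text = f"{rowtype}: {note}" if note else rowtype
                markers.append(SessionMarker(ts, UNKNOWN_MARKER, text))
            continue

        try:
            cage = int(row[2])
            counters = [int(v) for v in row[5:11]]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer field in {row!r}") from exc
        side, role = row[3], row[4]
        if side not in SIDES or role not in ROLES:
            raise FormatError(f"line {lineno}: bad side/role {side!r}/{role!r}")
        for name, value in zip(_COUNTER_FIELDS, counters):
            if value < 0:
                raise IntegrityError(f"line {lineno}: negative {name} ({value})")
        chan = (cage, side)
        if chan in last_ts and ts <= last_ts[chan]:
            raise IntegrityError(
                f"line {lineno}: non-monotone timestamp {row[1]} for cage "
                f"{cage} {side}"
            )
        last_ts[chan] = ts
        records.append(
            MinuteRecord(ts, cage, side, role, *counters)
        )

    return SessionLog(settings=settings, records=records, markers=markers)


def _pause_windows(markers: Sequence[SessionMarker]) -> list[tuple[datetime, datetime | None]]:
    windows = []
    open_pause: datetime | None = None
    for m in sorted(markers, key=lambda m: m.timestamp):
        if m.kind == "PAUSE" and open_pause is None:
            open_pause = m.timestamp
        elif m.kind == "RESUME" and open_pause is not None:
            windows.append((open_pause, m.timestamp))
            open_pause = None
    if open_pause is not None:
        windows.append((open_pause, None))
    return windows


def validate_log(log: SessionLog) -> list[Finding]:
    """Check a log against the counter and cadence invariants.

    Returns coded findings rather than raising; an empty list means clean.
    Codes: ``NEGATIVE_COUNTER``, ``BOUT_MIN_LICKS`` (a bout must contribute at
    least three licks), ``BOUT_LICK_DURATION_EXCESS`` (contact time within
    bouts cannot exceed bout duration), ``DUPLICATE_BIN`` and ``MISSING_BIN``
    (cadence gaps outside pause windows).
    """
    findings: list[Finding] = []
    bin_delta = timedelta(seconds=log.settings.bin_size_s)
    pauses = _pause_windows(log.markers)

    def paused(ts: datetime) -> bool:
        return any(start <= ts and (end is None or ts < end) for start, end in pauses)

    per_channel: dict[tuple[int, str], list[MinuteRecord]] = {}
    for r in log.records:
        per_channel.setdefault(r.channel, []).append(r)
        if any(getattr(r, f) < 0 for f in _COUNTER_FIELDS):
            findings.append(
                Finding("NEGATIVE_COUNTER", r.timestamp, r.cage, r.side)
            )
        if r.bout_licks < 3 * r.bout_count:
            findings.append(
                Finding(
                    "BOUT_MIN_LICKS",
                    r.timestamp,
                    r.cage,
                    r.side,
                    f"bout_licks={r.bout_licks} < 3*bout_count={3 * r.bout_count}",
                )
            )
        if r.bout_lick_duration_ms > r.bout_duration_ms:
            findings.append(
                Finding(
                    "BOUT_LICK_DURATION_EXCESS",
                    r.timestamp,
                    r.cage,
                    r.side,
                    f"{r.bout_lick_duration_ms} > {r.bout_duration_ms}",
                )
            )

    for (cage, side), recs in sorted(per_channel.items()):
        seen: set[datetime] = set()
        for r in recs:
            if r.timestamp in seen:
                findings.append(
                    Finding("DUPLICATE_BIN", r.timestamp, cage, side)
                )
            seen.add(r.timestamp)
        first, last = min(seen), max(seen)
        expected = first
        while expected <= last:
            if expected not in seen and not paused(expected):
                findings.append(Finding("MISSING_BIN", expected, cage, side))
            expected += bin_delta

    findings.sort(key=lambda f: (f.timestamp or datetime.min, f.code))
    return findings


def records_to_frame(records: Iterable[MinuteRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of minute records (one row per record)."""
    return pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in records],
            "cage": [r.cage for r in records],
            "side": [r.side for r in records],
            "role": [r.role for r in records],
            **{
                f: [getattr(r, f) for r in records]
                for f in _COUNTER_FIELDS
            },
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[MinuteRecord]:
    return [
        MinuteRecord(
            row.timestamp.to_pydatetime()
            if hasattr(row.timestamp, "to_pydatetime")
            else row.timestamp,
            int(row.cage),
            row.side,
            row.role,
            int(row.licks),
            int(row.lick_duration_ms),
            int(row.bout_count),
            int(row.bout_duration_ms),
            int(row.bout_licks),
            int(row.bout_lick_duration_ms),
        )
        for row in frame.itertuples(index=False)
    ]
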