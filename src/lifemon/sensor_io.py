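"""Readers, writers and windowing for binary object-sensor logs.

A single-resident home is instrumented with binary sensors embedded in
everyday objects (doors, cupboards, a refrigerator, a toilet flush...).
Each sensor reports activation intervals; the activity recognizer consumes
fixed-width time windows carrying one binary feature per sensor, set when
the sensor was active at any point inside the window.

All logs are plain CSV.  Timestamps are ISO-8601 at one-second resolution
(sub-second input is truncated) and are interpreted in the home's local
clock; days are calendar days with the boundary at midnight.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

#: Reserved activity label for windows no annotation (or prediction) covers.
IDLE_LABEL = "idle"

SECONDS_PER_DAY = 86_400


class LogFormatError(ValueError):
    """A log file violates the expected CSV schema or a record invariant."""


class UnknownSensorError(ValueError):
    """An event references a sensor absent from the deployment metadata."""


@dataclass(frozen=True)
class SensorSpec:
    """One deployed binary sensor: its id, host object and room."""

    sensor_id: str
    object_name: str
    location: str


@dataclass(frozen=True)
class SensorEvent:
    """A single activation interval of one sensor.

    The interval is treated as half-open ``[start, end)``; an event with
    ``start == end`` is an instantaneous trigger.  ``end`` may not precede
    ``start``.
    """

    sensor_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise LogFormatError(
                f"event for sensor {self.sensor_id!r} ends before it starts "
                f"({self.start.isoformat()} .. {self.end.isoformat()})"
            )


@dataclass(frozen=True)
class ActivityAnnotation:
    """Ground-truth record that one activity spanned [start, end)."""

    activity: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise LogFormatError(
                f"annotation {self.activity!r} has non-positive duration "
                f"({self.start.isoformat()} .. {self.end.isoformat()})"
            )


@dataclass(frozen=True)
class DailyMeasurement:
    """One scalar reading per day, e.g. weight in pounds or lighting in lux."""

    day: date
    name: str
    value: float


@dataclass
class LabeledWindow:
    """A fixed-width time window with per-sensor binary features.

    ``label`` is an activity name, :data:`IDLE_LABEL`, or ``None`` when the
    window has not been labeled yet.
    """

    window_start: datetime
    window_size: int
    features: dict[str, int]
    label: str | None = None

    @property
    def day(self) -> date:
        return self.window_start.date()

    @property
    def window_end(self) -> datetime:
        return self.window_start + timedelta(seconds=self.window_size)


@dataclass
class SensorStream:
    """A deployment (sensor metadata) plus its chronological event log."""

    sensors: list[SensorSpec]
    events: list[SensorEvent]

    def __post_init__(self) -> None:
        self._specs = {s.sensor_id: s for s in self.sensors}
        if len(self._specs) != len(self.sensors):
            raise LogFormatError("duplicate sensor_id in deployment metadata")
        for ev in self.events:
            if ev.sensor_id not in self._specs:
                raise UnknownSensorError(f"event references unknown sensor {ev.sensor_id!r}")
        self.events = sorted(self.events, key=lambda e: (e.start, e.sensor_id))

    def sensor_ids(self) -> list[str]:
        """Feature order: the deployment order of the metadata."""
        return [s.sensor_id for s in self.sensors]

    def location_of(self, sensor_id: str) -> str:
        try:
            return self._specs[sensor_id].location
        except KeyError:
            raise UnknownSensorError(f"unknown sensor {sensor_id!r}") from None

    def events_on(self, day: date) -> list[SensorEvent]:
        """Events whose activation starts on ``day``."""
        return [e for e in self.events if e.start.date() == day]


# ---------------------------------------------------------------------------
# CSV parsing helpers
# ---------------------------------------------------------------------------

def _rows(source: str | Path | IO[str]) -> Iterator[tuple[int, list[str]]]:
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            yield from _rows(handle)
        return
    for line_no, row in enumerate(csv.reader(source), start=1):
        if row and any(cell.strip() for cell in row):
            yield line_no, [cell.strip() for cell in row]


def _check_header(row: list[str], expected: Sequence[str], line_no: int) -> None:
    if [c.lower() for c in row] != list(expected):
        raise LogFormatError(
            f"line {line_no}: expected header {','.join(expected)!r}, got {','.join(row)!r}"
        )


def _parse_timestamp(text: str, line_no: int) -> datetime:
    try:
        ts = datetime.fromisoformat(text)
    except ValueError as exc:
        raise LogFormatError(f"line {line_no}: malformed timestamp {text!r}") from exc
    if ts.tzinfo is not None:
        # logs carry home-local wall-clock time; an explicit offset is dropped
        ts = ts.replace(tzinfo=None)
    return ts.replace(microsecond=0)


def _parse_date(text: str, line_no: int) -> date:
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise LogFormatError(f"line {line_no}: malformed date {text!r}") from exc


def _parse_float(text: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise LogFormatError(f"line {line_no}: malformed number {text!r}") from exc


# ---------------------------------------------------------------------------
# Log readers / writers
# ---------------------------------------------------------------------------

def read_sensor_metadata(source: str | Path | IO[str]) -> list[SensorSpec]:
    """Read a ``sensor_id,object_name,location`` CSV."""
    rows = _rows(source)
    line_no, header = next(rows)
    _check_header(header, ("sensor_id", "object_name", "location"), line_no)
    specs = []
    seen: set[str] = set()
    for line_no, row in rows:
        if len(row) != 3:
            raise LogFormatError(f"line {line_no}: expected 3 fields, got {len(row)}")
        if row[0] in seen:
            raise LogFormatError(f"line {line_no}: duplicate sensor_id {row[0]!r}")
        seen.add(row[0])
        specs.append(SensorSpec(*row))
    return specs


def read_event_log(
    source: str | Path | IO[str],
    sensors: Sequence[SensorSpec],
    dialect: str = "standard",
) -> SensorStream:
    """Read an activation-event CSV into a chronologically sorted stream.

    ``dialect="standard"`` expects ``sensor_id,start,end`` columns;
    ``dialect="kasteren"`` accepts the start/end-pair layout used by the
    published home datasets, ``start,end,sensor_id``.
    """
    if dialect == "standard":
        header = ("sensor_id", "start", "end")
        order = (0, 1, 2)
    elif dialect == "kasteren":
        header = ("start", "end", "sensor_id")
        order = (2, 0, 1)
    else:
        raise ValueError(f"unknown event-log dialect {dialect!r}")
    rows = _rows(source)
    line_no, first = next(rows)
    _check_header(first, header, line_no)
    known = {s.sensor_id for s in sensors}
    events = []
    for line_no, row in rows:
        if len(row) != 3:
            raise LogFormatError(f"line {line_no}: expected 3 fields, got {len(row)}")
        sensor_id = row[order[0]]
        start = _parse_timestamp(row[order[1]], line_no)
        end = _parse_timestamp(row[order[2]], line_no)
        if sensor_id not in known:
            raise UnknownSensorError(f"line {line_no}: unknown sensor {sensor_id!r}")
        if end < start:
            raise LogFormatError(f"line {line_no}: event ends before it starts")
        events.append(SensorEvent(sensor_id, start, end))
    return SensorStream(list(sensors), events)


def write_event_log(stream: SensorStream, dest: str | Path | IO[str]) -> None:
    _write_csv(
        dest,
        ("sensor_id", "start", "end"),
        ((e.sensor_id, e.start.isoformat(sep=" "), e.end.isoformat(sep=" ")) for e in stream.events),
    )


def read_annotation_log(source: str | Path | IO[str]) -> list[ActivityAnnotation]:
    """Read an ``activity,start,end`` CSV; annotations may not overlap."""
    rows = _rows(source)
    line_no, header = next(rows)
    _check_header(header, ("activity", "start", "end"), line_no)
    annotations = []
    for line_no, row in rows:
        if len(row) != 3:
            raise LogFormatError(f"line {line_no}: expected 3 fields, got {len(row)}")
        start = _parse_timestamp(row[1], line_no)
        end = _parse_timestamp(row[2], line_no)
        if end <= start:
            raise LogFormatError(f"line {line_no}: annotation has non-positive duration")
        annotations.append(ActivityAnnotation(row[0], start, end))
    annotations.sort(key=lambda a: a.start)
    for prev, nxt in zip(annotations, annotations[1:]):
        if nxt.start < prev.end:
            raise LogFormatError(
                f"annotations overlap: {prev.activity!r} ending {prev.end.isoformat()} vs "
                f"{nxt.activity!r} starting {nxt.start.isoformat()}"
            )
    return annotations


def write_annotation_log(annotations: Iterable[ActivityAnnotation], dest: str | Path | IO[str]) -> None:
    _write_csv(
        dest,
        ("activity", "start", "end"),
        ((a.activity, a.start.isoformat(sep=" "), a.end.isoformat(sep=" ")) for a in annotations),
    )


def read_measurement_log(source: str | Path | IO[str]) -> list[DailyMeasurement]:
    """Read a ``day,name,value`` CSV; at most one value per (day, name)."""
    rows = _rows(source)
    line_no, header = next(rows)
    _check_header(header, ("day", "name", "value"), line_no)
    out = []
    seen: set[tuple[date, str]] = set()
    for line_no, row in rows:
        if len(row) != 3:
            raise LogFormatError(f"line {line_no}: expected 3 fields, got {len(row)}")
        day = _parse_date(row[0], line_no)
        key = (day, row[1])
        if key in seen:
            raise LogFormatError(f"line {line_no}: duplicate measurement for {row[1]!r} on {day}")
        seen.add(key)
        out.append(DailyMeasurement(day, row[1], _parse_float(row[2], line_no)))
    return out


def write_measurement_log(measurements: Iterable[DailyMeasurement], dest: str | Path | IO[str]) -> None:
    _write_csv(
        dest,
        ("day", "name", "value"),
        ((m.day.isoformat(), m.name, repr(m.value)) for m in measurements),
    )


def write_sensor_metadata(sensors: Iterable[SensorSpec], dest: str | Path | IO[str]) -> None:
    _write_csv(
        dest,
        ("sensor_id", "object_name", "location"),
        ((s.sensor_id, s.object_name, s.location) for s in sensors),
    )


def _write_csv(dest: str | Path | IO[str], header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as handle:
            _write_csv(handle, header, rows)
        return
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def make_windows(stream: SensorStream, day: date, window_size: int) -> list[LabeledWindow]:
    """Tile ``day`` with half-open windows of ``window_size`` seconds.

    ``window_size`` must divide the 86,400 s day so the windows tile it
    exactly.  A feature is set to 1 iff an event of that sensor overlaps
    the window interval ``[start, start + window_size)``.
    """
    if window_size <= 0 or SECONDS_PER_DAY % window_size != 0:
        raise ValueError(
            f"window size {window_size} s must be a positive divisor of the 86,400 s day"
        )
    day_start = datetime.combine(day, time.min)
    n_windows = SECONDS_PER_DAY // window_size
    ids = stream.sensor_ids()
    windows = [
        LabeledWindow(day_start + timedelta(seconds=i * window_size), window_size, dict.fromkeys(ids, 0))
        for i in range(n_windows)
    ]
    for event in stream.events:
        for i in _covered_indices(event, day_start, window_size, n_windows):
            windows[i].features[event.sensor_id] = 1
    return windows


def _covered_indices(event: SensorEvent, day_start: datetime, window_size: int, n_windows: int) -> range:
    day_end = day_start + timedelta(seconds=SECONDS_PER_DAY)
    if event.start == event.end:  # instantaneous trigger
        if day_start <= event.start < day_end:
            i = int((event.start - day_start).total_seconds()) // window_size
            return range(i, i + 1)
        return range(0)
    start = max(event.start, day_start)
    end = min(event.end, day_end)
    if end <= start:
        return range(0)
    first = int((start - day_start).total_seconds()) // window_size
    last = -(-int((end - day_start).total_seconds()) // window_size)  # ceil
    return range(first, min(last, n_windows))


def assign_labels(
    windows: Sequence[LabeledWindow], annotations: Sequence[ActivityAnnotation]
) -> list[LabeledWindow]:
    """Label each window with the annotation covering most of it.

    Ties go to the annotation that starts earlier; windows no annotation
    overlaps get :data:`IDLE_LABEL`.  Labels are written in place and the
    window list is returned for chaining.
    """
    anns = sorted(annotations, key=lambda a: a.start)
    for window in windows:
        best: ActivityAnnotation | None = None
        best_overlap = 0.0
        for ann in anns:
            if ann.end <= window.window_start:
                continue
            if ann.start >= window.window_end:
                break
            overlap = (
                min(ann.end, window.window_end) - max(ann.start, window.window_start)
            ).total_seconds()
            if overlap > best_overlap:  # strict: earlier start wins ties
                best, best_overlap = ann, overlap
        window.label = best.activity if best is not None else IDLE_LABEL
    return list(windows)
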