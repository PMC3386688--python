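"""Daily activity-frequency statistics and graded deviation patterns.

The regularity model: for each monitored activity (a disease-influenced
activity, DIA) the daily activity frequency DAF is the number of episodes
performed that day (or the measured value, for scalar DIAs such as weight
or lighting).  Over a training period of D days the regular activity
frequency RAF is the mean DAF and the dispersion is the sample standard
deviation; DAFs are modeled as normally distributed around the RAF.  A
day's deviation is graded into five integer bands, the graded activity
frequency GAF in {-2..2}: z-scores inside [-1, 1] are "regular" (0), each
further standard deviation moves one band outward.  The ordered vector of
GAFs over the monitored DIAs is the daily activity pattern DAP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sensor_io import IDLE_LABEL, ActivityAnnotation, LabeledWindow, SensorStream

GAF_MIN = -2
GAF_MAX = 2

#: Verbal band names of the five GAF grades.
BAND_NAMES = {-2: "very low", -1: "low", 0: "regular", 1: "high", 2: "very high"}


@dataclass(frozen=True)
class Episode:
    """A maximal run of one activity: the unit counted by the DAF."""

    activity: str
    start: datetime
    end: datetime


@dataclass
class ActivityTimeline:
    """One day's non-overlapping, chronologically sorted episodes."""

    day: date
    episodes: list[Episode]


@dataclass(frozen=True)
class DafRecord:
    """Daily activity frequency: episode count, or measured value for scalar DIAs."""

    day: date
    dia: str
    value: float


@dataclass(frozen=True)
class ActivityProfile:
    """Training statistics of one DIA: mean (RAF) and dispersion of its DAF."""

    dia: str
    raf: float
    sd: float
    days: int


@dataclass(frozen=True)
class DailyActivityPattern:
    """Ordered vector of GAF grades over an explicit DIA list."""

    day: date
    dia_order: tuple[str, ...]
    gafs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.dia_order) != len(self.gafs):
            raise ValueError("one GAF per DIA required")
        if len(set(self.dia_order)) != len(self.dia_order):
            raise ValueError("duplicate DIA in pattern order")
        for dia, g in zip(self.dia_order, self.gafs):
            if not (GAF_MIN <= g <= GAF_MAX) or int(g) != g:
                raise ValueError(f"GAF for {dia!r} must be an integer in [{GAF_MIN}, {GAF_MAX}]")

    def gaf(self, dia: str) -> int:
        try:
            return self.gafs[self.dia_order.index(dia)]
        except ValueError:
            raise KeyError(f"DIA {dia!r} not in pattern") from None


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------

def windows_to_timeline(
    windows: Sequence[LabeledWindow], idle_tolerance: int = 1
) -> ActivityTimeline:
    """Merge consecutive same-label windows of one day into episodes.

    Idle windows are dropped; a run of at most ``idle_tolerance``
    intervening idle windows does not split an episode, so a one-window
    recognition dropout inside a long activity is bridged.  A window of a
    different activity always ends the current episode.
    """
    windows = sorted(windows, key=lambda w: w.window_start)
    if not windows:
        raise ValueError("no windows given")
    day = windows[0].day
    episodes: list[Episode] = []
    cur_label: str | None = None
    cur_start: datetime | None = None
    cur_end: datetime | None = None
    idle_run = 0
    for window in windows:
        label = window.label
        if label is None:
            raise ValueError("windows must be labeled before building a timeline")
        if label == IDLE_LABEL:
            idle_run += 1
            continue
        contiguous = (
            cur_end is not None
            and (window.window_start - cur_end).total_seconds() == idle_run * window.window_size
        )
        if label == cur_label and idle_run <= idle_tolerance and contiguous:
            cur_end = window.window_end
        else:
            if cur_label is not None:
                episodes.append(Episode(cur_label, cur_start, cur_end))
            cur_label, cur_start, cur_end = label, window.window_start, window.window_end
        idle_run = 0
    if cur_label is not None:
        episodes.append(Episode(cur_label, cur_start, cur_end))
    return ActivityTimeline(day, episodes)


def annotations_to_timeline(annotations: Sequence[ActivityAnnotation], day: date) -> ActivityTimeline:
    """Build a ground-truth timeline from the annotations starting on ``day``."""
    episodes = [
        Episode(a.activity, a.start, a.end)
        for a in sorted(annotations, key=lambda a: a.start)
        if a.start.date() == day
    ]
    return ActivityTimeline(day, episodes)


# ---------------------------------------------------------------------------
# DAF / RAF / GAF / DAP
# ---------------------------------------------------------------------------

def compute_daf(
    timeline: ActivityTimeline, dia: str, vocabulary: Iterable[str] | None = None
) -> DafRecord:
    """Count the day's episodes of ``dia``.

    When a ``vocabulary`` of known DIAs is supplied, asking for an activity
    outside it is an error rather than a silent zero.
    """
    if vocabulary is not None and dia not in set(vocabulary):
        raise KeyError(f"unknown DIA {dia!r}")
    count = sum(ep.activity == dia for ep in timeline.episodes)
    return DafRecord(timeline.day, dia, float(count))


def movement_daf(stream: SensorStream, day: date) -> DafRecord:
    """Movement DAF: transitions between distinct sensor locations in a day.

    Events are ordered by activation start; each adjacent pair whose host
    sensors sit in different rooms counts as one transition.
    """
    locations = [stream.location_of(e.sensor_id) for e in stream.events_on(day)]
    transitions = sum(a != b for a, b in zip(locations, locations[1:]))
    return DafRecord(day, "movement", float(transitions))


def compute_raf(dafs: Sequence[DafRecord] | Sequence[float]) -> float:
    """Regular activity frequency: the arithmetic mean DAF over training days."""
    values = _values(dafs)
    if len(values) == 0:
        raise ValueError("cannot compute a RAF from an empty training series")
    return float(np.mean(values))


def fit_profile(dafs: Sequence[DafRecord] | Sequence[float], dia: str | None = None) -> ActivityProfile:
    """Fit the normal regularity model: RAF plus sample standard deviation.

    With a single training day the dispersion cannot be estimated; it is
    set to 0 and a warning is issued (grading then degenerates to an
    exact-match rule, see :func:`grade_gaf`).
    """
    values = _values(dafs)
    if len(values) == 0:
        raise ValueError("cannot fit a profile from an empty training series")
    if dia is None:
        dias = {d.dia for d in dafs if isinstance(d, DafRecord)}
        if len(dias) > 1:
            raise ValueError(f"training series mixes DIAs: {sorted(dias)}")
        dia = dias.pop() if dias else "?"
    raf = float(np.mean(values))
    if len(values) >= 2:
        sd = float(np.std(values, ddof=1))
    else:
        warnings.warn(
            f"single training day for {dia!r}: dispersion set to 0", stacklevel=2
        )
        sd = 0.0
    return ActivityProfile(dia, raf, sd, len(values))


def _values(dafs: Sequence[DafRecord] | Sequence[float]) -> np.ndarray:
    return np.array(
        [d.value if isinstance(d, DafRecord) else float(d) for d in dafs], dtype=float
    )


def grade_gaf(daf: DafRecord | float, profile: ActivityProfile) -> int:
    """Grade a day's DAF against its profile into the five GAF bands.

    The z-score ``(value - raf) / sd`` maps to bands ``z < -2 -> -2``,
    ``-2 <= z < -1 -> -1``, ``-1 <= z <= 1 -> 0`` (the closed regular
    band), ``1 < z <= 2 -> 1`` and ``z > 2 -> 2``; boundary values fall in
    the more-regular band.  With a degenerate profile (``sd == 0``) any
    deviation from the RAF is extreme by definition: the grade is 0 on an
    exact match and ±2 by the sign of the deviation otherwise.
    """
    value = daf.value if isinstance(daf, DafRecord) else float(daf)
    if profile.sd == 0:
        if value == profile.raf:
            return 0
        return GAF_MAX if value > profile.raf else GAF_MIN
    z = (value - profile.raf) / profile.sd
    if z < -2:
        return -2
    if z < -1:
        return -1
    if z <= 1:
        return 0
    if z <= 2:
        return 1
    return 2


def build_dap(
    day: date, gafs: Mapping[str, int], dia_order: Sequence[str]
) -> DailyActivityPattern:
    """Assemble the day's GAFs into a pattern vector in the declared DIA order."""
    order = tuple(dia_order)
    if len(set(order)) != len(order):
        raise ValueError(f"duplicate DIA in order: {list(order)}")
    missing = [dia for dia in order if dia not in gafs]
    if missing:
        raise KeyError(f"missing GAF for DIAs: {missing}")
    return DailyActivityPattern(day, order, tuple(int(gafs[dia]) for dia in order))


def format_daf_delta(value: float, raf: float) -> str:
    """Render a DAF with its day-over-average change, e.g. ``2(▲ 1)``.

    The arrow marks an increase (▲) or decrease (▼) of the day's value
    relative to the rounded RAF; an unchanged value renders plain.
    """
    delta = float(value) - round(float(raf))
    if delta == 0:
        return _format_number(value)
    arrow = "▲" if delta > 0 else "▼"
    return f"{_format_number(value)}({arrow} {_format_number(abs(delta))})"


def _format_number(x: float) -> str:
    x = float(x)
    return str(int(x)) if x.is_integer() else f"{x:g}"
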