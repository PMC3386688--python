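"""Seeded synthetic smart-home datasets for end-to-end pipeline testing.

The generator emulates a single-resident home: each day, every activity
draws an episode count from a rounded normal distribution (matching the
normality assumption the regularity model makes about daily frequencies),
episodes are placed without overlap uniformly over the free time of the
day, and each episode activates its characteristic object sensors.  Daily
scalar readings (weight in pounds, lighting in lux) are drawn around
configurable means.  A drift specification perturbs the episode rates and
scalar means on selected days, emulating the onset of disease-shaped
irregularity while leaving other days untouched.

Everything is reproducible from the profile's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np

from .sensor_io import (
    SECONDS_PER_DAY,
    ActivityAnnotation,
    DailyMeasurement,
    LabeledWindow,
    SensorEvent,
    SensorSpec,
    SensorStream,
    assign_labels,
    make_windows,
)


class SimulationError(RuntimeError):
    """The requested day cannot be scheduled (activities exceed 24 h)."""


@dataclass(frozen=True)
class ActivitySpec:
    """Daily behavior of one activity.

    ``mean_count`` is the expected number of episodes per day (the rate
    whose long-run mean the RAF should recover), ``count_sd`` its
    day-to-day dispersion; durations are in seconds and are clipped to
    ``mean_duration ± 3 * duration_sd`` (and at least 30 s) so a single
    tail draw cannot consume the day.
    """

    name: str
    mean_count: float
    count_sd: float
    mean_duration: float
    duration_sd: float

    def __post_init__(self) -> None:
        if self.mean_count < 0 or self.count_sd < 0:
            raise ValueError(f"{self.name!r}: negative count parameters")
        if self.mean_duration < 30 or self.duration_sd < 0:
            raise ValueError(f"{self.name!r}: durations must be >= 30 s")


@dataclass(frozen=True)
class ScalarSpec:
    """Mean and day-to-day standard deviation of one scalar DIA."""

    mean: float
    sd: float


@dataclass(frozen=True)
class DriftSpec:
    """Disease-shaped perturbation applied on selected days only.

    Count DIAs get their episode rate multiplied; scalar DIAs get their
    mean shifted by ``offset * sd``.  All multipliers must be >= 0.
    """

    disease: str
    days: frozenset[date]
    count_multipliers: Mapping[str, float] = field(default_factory=dict)
    scalar_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mult in self.count_multipliers.items():
            if mult < 0:
                raise ValueError(f"negative multiplier for {name!r}")


@dataclass(frozen=True)
class SimProfile:
    """Full description of a simulated deployment."""

    activities: tuple[ActivitySpec, ...]
    object_map: Mapping[str, tuple[tuple[str, float], ...]]
    sensors: tuple[SensorSpec, ...]
    scalar_dias: Mapping[str, ScalarSpec] = field(default_factory=dict)
    seed: int = 0
    false_event_rate: float = 0.0  # expected spurious activations / sensor / day
    miss_prob: float = 0.0  # chance an episode's object fails to fire
    count_model: str = "normal"  # "normal" (rounded, truncated at 0) or "poisson"
    drift: DriftSpec | None = None

    def __post_init__(self) -> None:
        known = {s.sensor_id for s in self.sensors}
        for activity, objects in self.object_map.items():
            for sensor_id, p in objects:
                if sensor_id not in known:
                    raise ValueError(f"{activity!r} maps to unknown sensor {sensor_id!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"firing probability {p} outside [0, 1]")
        if self.count_model not in ("normal", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")

    def activity_names(self) -> list[str]:
        return [a.name for a in self.activities]


def inject_drift(profile: SimProfile, drift: DriftSpec) -> SimProfile:
    """Return a copy of ``profile`` with ``drift`` active on its affected days."""
    names = set(profile.activity_names())
    unknown = [n for n in drift.count_multipliers if n not in names]
    unknown += [n for n in drift.scalar_offsets if n not in profile.scalar_dias]
    if unknown:
        raise KeyError(f"drift targets unknown DIAs: {sorted(unknown)}")
    return replace(profile, drift=drift)


def simulate_days(
    profile: SimProfile, days: int, start: date = date(2024, 1, 1)
) -> tuple[SensorStream, list[ActivityAnnotation], list[DailyMeasurement]]:
    """Generate ``days`` consecutive days of events, annotations and readings.

    Episode placement is uniform over the arrangements of non-overlapping
    intervals in a day (random episode order, Dirichlet-distributed gaps
    over the free time); a day whose drawn episodes cannot fit raises
    :class:`SimulationError`.  Every emitted sensor event lies within its
    episode's interval.  Output is fully determined by the profile's seed.
    """
    if days < 1:
        raise ValueError("need at least one day")
    rng = np.random.default_rng(profile.seed)
    events: list[SensorEvent] = []
    annotations: list[ActivityAnnotation] = []
    measurements: list[DailyMeasurement] = []
    for offset in range(days):
        day = start + timedelta(days=offset)
        drifted = profile.drift is not None and day in profile.drift.days
        day_start = datetime.combine(day, time.min)

        episodes: list[tuple[str, int]] = []
        for activity in profile.activities:
            rate = activity.mean_count
            if drifted:
                rate *= profile.drift.count_multipliers.get(activity.name, 1.0)
            if profile.count_model == "poisson":
                count = int(rng.poisson(rate))
            else:
                count = max(0, int(round(rng.normal(rate, activity.count_sd))))
            for _ in range(count):
                duration = rng.normal(activity.mean_duration, activity.duration_sd)
                low = max(30.0, activity.mean_duration - 3 * activity.duration_sd)
                high = activity.mean_duration + 3 * activity.duration_sd
                episodes.append((activity.name, int(round(min(max(duration, low), high)))))

        total = sum(d for _, d in episodes)
        if total > SECONDS_PER_DAY:
            raise SimulationError(
                f"{day}: scheduled activity ({total} s) exceeds the {SECONDS_PER_DAY} s day"
            )
        order = rng.permutation(len(episodes))
        gaps = rng.dirichlet(np.ones(len(episodes) + 1)) * (SECONDS_PER_DAY - total)
        cursor = 0.0
        for idx, gap in zip(order, gaps):
            name, duration = episodes[idx]
            cursor += gap
            ep_start = day_start + timedelta(seconds=int(cursor))
            ep_end = ep_start + timedelta(seconds=duration)
            annotations.append(ActivityAnnotation(name, ep_start, ep_end))
            pad = min(duration // 4, 60)
            for sensor_id, p in profile.object_map.get(name, ()):
                if rng.random() < p * (1.0 - profile.miss_prob):
                    lead = int(rng.integers(0, pad + 1))
                    tail = int(rng.integers(0, pad + 1))
                    events.append(
                        SensorEvent(
                            sensor_id,
                            ep_start + timedelta(seconds=lead),
                            ep_end - timedelta(seconds=tail),
                        )
                    )
            cursor += duration

        if profile.false_event_rate > 0:
            for spec in profile.sensors:
                for _ in range(int(rng.poisson(profile.false_event_rate))):
                    t0 = int(rng.integers(0, SECONDS_PER_DAY - 30))
                    events.append(
                        SensorEvent(
                            spec.sensor_id,
                            day_start + timedelta(seconds=t0),
                            day_start + timedelta(seconds=t0 + 30),
                        )
                    )

        for name, scalar in profile.scalar_dias.items():
            mean = scalar.mean
            if drifted:
                mean += profile.drift.scalar_offsets.get(name, 0.0) * scalar.sd
            measurements.append(DailyMeasurement(day, name, float(rng.normal(mean, scalar.sd))))

    return SensorStream(list(profile.sensors), events), annotations, measurements


# ---------------------------------------------------------------------------
# Stock profiles and fixtures
# ---------------------------------------------------------------------------

def default_profile(
    seed: int = 0, *, false_event_rate: float = 0.0, miss_prob: float = 0.0
) -> SimProfile:
    """A single-resident home with realistic daily rhythms.

    Nine object sensors across four rooms; six activities with typical
    daily rates (three meals, five toilet visits, fragmented sleep
    occupancy, one shower, one outing, two medication intakes) and daily
    weight (189.8 ± 1 lb) and lighting (300 ± 30 lux) readings.
    """
    sensors = (
        SensorSpec("bed", "Bed", "bedroom"),
        SensorSpec("fridge", "Refrigerator", "kitchen"),
        SensorSpec("stove", "Stove", "kitchen"),
        SensorSpec("cabinet", "Cabinet", "kitchen"),
        SensorSpec("water_glass", "Water glass", "kitchen"),
        SensorSpec("purifier", "Purifier", "kitchen"),
        SensorSpec("toilet_flush", "Toilet flush", "bathroom"),
        SensorSpec("shower_faucet", "Shower faucet", "bathroom"),
        SensorSpec("front_door", "Front door", "entrance"),
    )
    activities = (
        ActivitySpec("sleeping", 1.5, 0.5, 4 * 3600, 1800),
        ActivitySpec("eating", 3.0, 0.8, 1500, 300),
        ActivitySpec("toileting", 5.0, 1.0, 300, 60),
        ActivitySpec("showering", 1.0, 0.3, 600, 120),
        ActivitySpec("going out", 1.0, 0.5, 5400, 1200),
        ActivitySpec("taking medication", 2.0, 0.4, 180, 30),
    )
    object_map = {
        "sleeping": (("bed", 1.0),),
        "eating": (("fridge", 0.9), ("stove", 0.6)),
        "toileting": (("toilet_flush", 1.0),),
        "showering": (("shower_faucet", 1.0),),
        "going out": (("front_door", 1.0),),
        "taking medication": (("cabinet", 1.0), ("water_glass", 1.0), ("purifier", 1.0)),
    }
    scalar_dias = {"weight": ScalarSpec(189.8, 1.0), "lighting": ScalarSpec(300.0, 30.0)}
    return SimProfile(
        activities=activities,
        object_map=object_map,
        sensors=sensors,
        scalar_dias=scalar_dias,
        seed=seed,
        false_event_rate=false_event_rate,
        miss_prob=miss_prob,
    )


def diabetes_drift(days: Sequence[date] | frozenset[date]) -> DriftSpec:
    """Diabetes-shaped irregularity: more toileting, eating and sleeping,
    and a weight drop of three daily standard deviations."""
    return DriftSpec(
        disease="diabetes",
        days=frozenset(days),
        count_multipliers={"toileting": 3.0, "eating": 2.0, "sleeping": 1.5},
        scalar_offsets={"weight": -3.0},
    )


@dataclass
class SeparableFixture:
    """A deterministic, perfectly separable labeled dataset.

    Every activity fires one unique sensor set with probability 1 on a
    schedule that repeats identically each day and is aligned to a
    10-minute grid, so window features identify the activity exactly at
    both 60 s and 600 s window sizes.
    """

    stream: SensorStream
    annotations: list[ActivityAnnotation]
    days: list[date]

    @property
    def sensors(self) -> list[SensorSpec]:
        return self.stream.sensors

    def labeled_windows(self, window_size: int = 60) -> list[LabeledWindow]:
        windows: list[LabeledWindow] = []
        for day in self.days:
            windows.extend(make_windows(self.stream, day, window_size))
        return assign_labels(windows, self.annotations)


#: (activity, start minute of day, end minute of day, sensor ids) — 10-min grid
_FIXTURE_SCHEDULE = (
    ("sleeping", 0, 7 * 60, ("Bed",)),
    ("Taking medication", 8 * 60, 8 * 60 + 10, ("Cabinet", "Water glass", "Purifier")),
    ("eating", 9 * 60, 9 * 60 + 30, ("Fridge",)),
    ("toileting", 10 * 60, 10 * 60 + 10, ("Toilet flush",)),
    ("showering", 11 * 60, 11 * 60 + 10, ("Shower faucet",)),
    ("eating", 13 * 60, 13 * 60 + 30, ("Fridge",)),
    ("going out", 14 * 60, 15 * 60, ("Front door",)),
    ("toileting", 16 * 60, 16 * 60 + 10, ("Toilet flush",)),
    ("eating", 19 * 60, 19 * 60 + 30, ("Fridge",)),
)


def make_separable_fixture(days: int = 2, start: date = date(2024, 3, 4)) -> SeparableFixture:
    """Build the noise-free fixture: unique sensors per activity, identical
    daily schedule, including a "Taking medication" episode that activates
    Cabinet + Water glass + Purifier."""
    rooms = {
        "Bed": "bedroom",
        "Cabinet": "kitchen",
        "Water glass": "kitchen",
        "Purifier": "kitchen",
        "Fridge": "kitchen",
        "Toilet flush": "bathroom",
        "Shower faucet": "bathroom",
        "Front door": "entrance",
    }
    sensors = [SensorSpec(sid, sid, room) for sid, room in rooms.items()]
    events: list[SensorEvent] = []
    annotations: list[ActivityAnnotation] = []
    day_list = [start + timedelta(days=i) for i in range(days)]
    for day in day_list:
        day_start = datetime.combine(day, time.min)
        for activity, m0, m1, sensor_ids in _FIXTURE_SCHEDULE:
            ep_start = day_start + timedelta(minutes=m0)
            ep_end = day_start + timedelta(minutes=m1)
            annotations.append(ActivityAnnotation(activity, ep_start, ep_end))
            for sid in sensor_ids:
                events.append(SensorEvent(sid, ep_start, ep_end))
    return SeparableFixture(SensorStream(sensors, events), annotations, day_list)
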