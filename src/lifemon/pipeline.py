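"""End-to-end orchestration: train, monitor, evaluate, simulate.

The three hierarchically connected stages — activity classification,
activity-pattern generation and disease prediction — are wired here:

* ``train``: fit the decision-tree classifier on annotated training days
  and fit one regularity profile (RAF, dispersion) per monitored DIA from
  the ground-truth annotations, sensor locations (movement) and daily
  scalar readings; persist both.
* ``monitor``: classify each monitoring day's windows, merge them into
  episodes, compute DAFs, grade GAFs, assemble the daily activity pattern
  per disease and score the risk; persist tables and reports.
* ``evaluate``: leave-one-day-out cross-validation of the classifier at
  one or more window sizes.
* ``simulate``: write a synthetic deployment to the standard CSV logs.

All functions are importable and file-based; the ``lifemon`` command in
:mod:`lifemon.cli` is a thin wrapper around them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import sensor_io
from .activity_classifier import DecisionTree, EvalReport, leave_one_day_out, train_tree
from .disease_risk import (
    DiseaseDefinition,
    RiskReport,
    daily_risk_series,
    diabetes_definition,
    load_disease_definitions,
)
from .pattern_stats import (
    ActivityProfile,
    DafRecord,
    annotations_to_timeline,
    build_dap,
    compute_daf,
    fit_profile,
    format_daf_delta,
    grade_gaf,
    movement_daf,
    windows_to_timeline,
)
from .sensor_io import SensorStream, assign_labels, make_windows
from .synthetic_data import SimProfile, default_profile, diabetes_drift, inject_drift, simulate_days

logger = logging.getLogger("lifemon")

#: DIA name with a dedicated location-transition definition.
MOVEMENT_DIA = "movement"


class PipelineError(RuntimeError):
    """A pipeline stage cannot run with the given configuration."""


@dataclass
class PipelineConfig:
    """File locations and run parameters shared by the pipeline commands."""

    sensors: Path
    events: Path
    diseases: Path
    out_dir: Path
    annotations: Path | None = None
    measurements: Path | None = None
    window_size: int = 60
    train_days: tuple[date, date] | None = None  # inclusive range
    monitor_days: tuple[date, date] | None = None
    eval_window_sizes: tuple[int, ...] = (60, 600)
    min_leaf: int = 2
    prune: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_days and self.monitor_days:
            t0, t1 = self.train_days
            m0, m1 = self.monitor_days
            if t0 <= m1 and m0 <= t1:
                raise PipelineError("training and monitoring day ranges must be disjoint")

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        path = Path(source)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        doc = json.loads(path.read_text(encoding="utf-8"))
        base = path.parent

        def _path(key: str, required: bool = True) -> Path | None:
            if key not in doc:
                if required:
                    raise PipelineError(f"config missing required path {key!r}")
                return None
            p = Path(doc[key])
            return p if p.is_absolute() else base / p

        def _range(key: str) -> tuple[date, date] | None:
            if key not in doc or doc[key] is None:
                return None
            lo, hi = doc[key]
            return (date.fromisoformat(lo), date.fromisoformat(hi))

        return cls(
            sensors=_path("sensors"),
            events=_path("events"),
            diseases=_path("diseases"),
            out_dir=_path("out_dir"),
            annotations=_path("annotations", required=False),
            measurements=_path("measurements", required=False),
            window_size=int(doc.get("window_size", 60)),
            train_days=_range("train_days"),
            monitor_days=_range("monitor_days"),
            eval_window_sizes=tuple(doc.get("eval_window_sizes", (60, 600))),
            min_leaf=int(doc.get("min_leaf", 2)),
            prune=bool(doc.get("prune", False)),
            seed=int(doc.get("seed", 0)),
        )


def _days_in(span: tuple[date, date]) -> list[date]:
    lo, hi = span
    return [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]


def _load_inputs(config: PipelineConfig, *, need_annotations: bool, need_measurements: bool):
    for attr in ("sensors", "events", "diseases"):
        path = getattr(config, attr)
        if not Path(path).exists():
            raise PipelineError(f"missing {attr} file: {path}")
    sensors = sensor_io.read_sensor_metadata(config.sensors)
    stream = sensor_io.read_event_log(config.events, sensors)
    diseases = load_disease_definitions(Path(config.diseases))
    annotations = None
    if config.annotations is not None and Path(config.annotations).exists():
        annotations = sensor_io.read_annotation_log(config.annotations)
    elif need_annotations:
        raise PipelineError(f"missing annotation file: {config.annotations}")
    measurements = None
    if config.measurements is not None and Path(config.measurements).exists():
        measurements = sensor_io.read_measurement_log(config.measurements)
    elif need_measurements:
        raise PipelineError(f"missing measurement file: {config.measurements}")
    return stream, annotations, measurements, diseases


def _scalar_names(measurements, diseases) -> set[str]:
    measured = {m.name for m in (measurements or [])}
    dias = {dia for d in diseases for dia in d.dias}
    return measured & dias


# ---------------------------------------------------------------------------
# Profile fitting (shared by train and the in-memory study runner)
# ---------------------------------------------------------------------------

def fit_profiles(
    dias: Sequence[str],
    stream: SensorStream,
    annotations: Sequence[sensor_io.ActivityAnnotation],
    measurements: Sequence[sensor_io.DailyMeasurement] | None,
    days: Sequence[date],
) -> dict[str, ActivityProfile]:
    """Fit one regularity profile per DIA over the training days.

    Count DIAs are counted from the ground-truth annotations, movement
    from sensor location transitions, scalar DIAs from the daily
    measurement log.
    """
    by_day_name = {(m.day, m.name): m.value for m in (measurements or [])}
    scalar_names = {m.name for m in (measurements or [])}
    profiles: dict[str, ActivityProfile] = {}
    for dia in dias:
        series: list[DafRecord] = []
        for day in days:
            if dia == MOVEMENT_DIA:
                series.append(movement_daf(stream, day))
            elif dia in scalar_names:
                if (day, dia) not in by_day_name:
                    raise PipelineError(f"no {dia!r} measurement for training day {day}")
                series.append(DafRecord(day, dia, by_day_name[(day, dia)]))
            else:
                timeline = annotations_to_timeline(annotations, day)
                series.append(compute_daf(timeline, dia))
        profiles[dia] = fit_profile(series, dia)
    return profiles


def _daily_dafs(
    dias: Sequence[str],
    stream: SensorStream,
    tree: DecisionTree,
    measurements: Sequence[sensor_io.DailyMeasurement] | None,
    day: date,
    window_size: int,
) -> dict[str, DafRecord]:
    """Recognize one monitoring day and compute its DAF per DIA."""
    by_name = {m.name: m.value for m in (measurements or []) if m.day == day}
    windows = make_windows(stream, day, window_size)
    for window in windows:
        window.label = tree.predict(window.features)
    timeline = windows_to_timeline(windows)
    dafs: dict[str, DafRecord] = {}
    for dia in dias:
        if dia == MOVEMENT_DIA:
            dafs[dia] = movement_daf(stream, day)
        elif dia in by_name:
            dafs[dia] = DafRecord(day, dia, by_name[dia])
        else:
            dafs[dia] = compute_daf(timeline, dia)
    return dafs


# ---------------------------------------------------------------------------
# Commands
# ---------------------------------------------------------------------------

def train_pipeline(config: PipelineConfig) -> tuple[DecisionTree, dict[str, ActivityProfile]]:
    """Fit and persist the classifier and the per-DIA regularity profiles."""
    if config.train_days is None:
        raise PipelineError("config must set a training day range")
    stream, annotations, measurements, diseases = _load_inputs(
        config, need_annotations=True, need_measurements=False
    )
    days = _days_in(config.train_days)
    annotated_days = {a.start.date() for a in annotations}
    if not annotated_days & set(days):
        raise PipelineError("annotations do not cover the training range")

    windows = []
    for day in days:
        day_windows = make_windows(stream, day, config.window_size)
        windows.extend(assign_labels(day_windows, annotations))
        logger.info("train: windowed day %s", day)
    tree = train_tree(windows, min_leaf=config.min_leaf, prune=config.prune)

    dias = sorted({dia for d in diseases for dia in d.dias})
    profiles = fit_profiles(dias, stream, annotations, measurements, days)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree.save(out / "tree.json")
    pd.DataFrame(
        [
            {"dia": p.dia, "raf": p.raf, "sd": p.sd, "days": p.days}
            for p in profiles.values()
        ]
    ).to_csv(out / "profiles.csv", index=False)
    logger.info("train: persisted tree.json and profiles.csv to %s", out)
    return tree, profiles


def load_artifacts(out_dir: str | Path) -> tuple[DecisionTree, dict[str, ActivityProfile]]:
    out = Path(out_dir)
    tree_path = out / "tree.json"
    profile_path = out / "profiles.csv"
    if not tree_path.exists() or not profile_path.exists():
        raise PipelineError(f"missing trained model in {out}; run train first")
    tree = DecisionTree.load(tree_path)
    table = pd.read_csv(profile_path)
    profiles = {
        row.dia: ActivityProfile(row.dia, float(row.raf), float(row.sd), int(row.days))
        for row in table.itertuples()
    }
    return tree, profiles


def monitor_pipeline(config: PipelineConfig) -> list[RiskReport]:
    """Score each monitoring day against every registered disease.

    Persists ``daf_table.csv`` (day, dia, daf, raf, sd, gaf), a
    human-readable ``daf_display.csv`` with day-over-average deltas,
    ``daps.json`` and ``risk_reports.jsonl``.
    """
    if config.monitor_days is None:
        raise PipelineError("config must set a monitoring day range")
    stream, _, measurements, diseases = _load_inputs(
        config, need_annotations=False, need_measurements=False
    )
    tree, profiles = load_artifacts(config.out_dir)
    days = _days_in(config.monitor_days)
    dias = sorted({dia for d in diseases for dia in d.dias})
    missing = [dia for dia in dias if dia not in profiles]
    if missing:
        raise PipelineError(f"no trained profile for DIAs: {missing}")

    rows = []
    daps_by_day = []
    reports: list[RiskReport] = []
    for day in days:
        dafs = _daily_dafs(dias, stream, tree, measurements, day, config.window_size)
        gafs = {dia: grade_gaf(dafs[dia], profiles[dia]) for dia in dias}
        for dia in dias:
            p = profiles[dia]
            rows.append(
                {
                    "day": day.isoformat(),
                    "dia": dia,
                    "daf": dafs[dia].value,
                    "raf": p.raf,
                    "sd": p.sd,
                    "gaf": gafs[dia],
                    "display": format_daf_delta(dafs[dia].value, p.raf),
                }
            )
        day_reports = []
        for disease in diseases:
            dap = build_dap(day, gafs, disease.dias)
            day_reports.extend(daily_risk_series([disease], [dap]))
        reports.extend(day_reports)
        daps_by_day.append(
            {"day": day.isoformat(), "gafs": {dia: gafs[dia] for dia in dias}}
        )
        logger.info(
            "monitor: day %s risks %s",
            day,
            {r.disease: round(r.risk, 3) for r in day_reports},
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    columns = ["day", "dia", "daf", "raf", "sd", "gaf"]
    table = pd.DataFrame(rows, columns=columns + ["display"])
    table[columns].to_csv(out / "daf_table.csv", index=False)
    if len(table):
        display = table.pivot(index="day", columns="dia", values="display")
    else:
        display = pd.DataFrame()
    display.to_csv(out / "daf_display.csv")
    (out / "daps.json").write_text(json.dumps(daps_by_day, indent=1), encoding="utf-8")
    with open(out / "risk_reports.jsonl", "w", encoding="utf-8") as handle:
        for report in reports:
            handle.write(json.dumps(report.to_json_dict()) + "\n")
    return reports


def evaluate_pipeline(config: PipelineConfig) -> dict[int, EvalReport]:
    """Leave-one-day-out evaluation at each configured window size."""
    stream, annotations, _, _ = _load_inputs(
        config, need_annotations=True, need_measurements=False
    )
    if config.train_days is not None:
        days = [d for d in _days_in(config.train_days)]
    else:
        days = sorted({a.start.date() for a in annotations})
    if len(days) < 2:
        raise PipelineError("evaluation needs at least two annotated days")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[int, EvalReport] = {}
    for window_size in config.eval_window_sizes:
        windows = []
        for day in days:
            windows.extend(assign_labels(make_windows(stream, day, window_size), annotations))
        report = leave_one_day_out(
            windows, window_size, min_leaf=config.min_leaf, prune=config.prune
        )
        reports[window_size] = report
        (out / f"eval_{window_size}s.json").write_text(
            json.dumps(report.to_json_dict(), indent=1), encoding="utf-8"
        )
        logger.info("evaluate: window %ss accuracy %.4f", window_size, report.accuracy)
    return reports


def simulate_pipeline(
    out_dir: str | Path,
    days: int,
    seed: int = 0,
    *,
    start: date = date(2024, 1, 1),
    profile: SimProfile | None = None,
    drift: Mapping | None = None,
) -> None:
    """Write a synthetic deployment to the standard CSV logs.

    ``drift``, when given, is a mapping with keys ``disease``, ``days``
    (ISO dates), ``count_multipliers`` and ``scalar_offsets`` mirroring
    :class:`lifemon.synthetic_data.DriftSpec`.
    """
    from .synthetic_data import DriftSpec  # local import to keep module load light

    if profile is None:
        profile = default_profile(seed=seed)
    if drift:
        spec = DriftSpec(
            disease=drift.get("disease", "drift"),
            days=frozenset(date.fromisoformat(d) for d in drift["days"]),
            count_multipliers=drift.get("count_multipliers", {}),
            scalar_offsets=drift.get("scalar_offsets", {}),
        )
        profile = inject_drift(profile, spec)
    stream, annotations, measurements = simulate_days(profile, days, start=start)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sensor_io.write_sensor_metadata(stream.sensors, out / "sensors.csv")
    sensor_io.write_event_log(stream, out / "events.csv")
    sensor_io.write_annotation_log(annotations, out / "annotations.csv")
    sensor_io.write_measurement_log(measurements, out / "measurements.csv")
    logger.info("simulate: wrote %d days to %s", days, out)


# ---------------------------------------------------------------------------
# In-memory end-to-end study
# ---------------------------------------------------------------------------

def run_drift_study(
    seed: int = 0,
    *,
    train_days: int = 25,
    clean_days: int = 5,
    drift_days: int = 5,
    window_size: int = 60,
    start: date = date(2024, 1, 1),
) -> dict:
    """Train on clean days, monitor clean + diabetes-drift days, in memory.

    Returns the per-day diabetes risks split into the clean and drift
    monitoring groups, for parameter-recovery checks and demos.
    """
    total = train_days + clean_days + drift_days
    all_days = [start + timedelta(days=i) for i in range(total)]
    drift_dates = all_days[train_days + clean_days :]
    profile = inject_drift(default_profile(seed=seed), diabetes_drift(drift_dates))
    stream, annotations, measurements = simulate_days(profile, total, start=start)
    disease = diabetes_definition()

    training = all_days[:train_days]
    windows = []
    for day in training:
        windows.extend(assign_labels(make_windows(stream, day, window_size), annotations))
    tree = train_tree(windows)
    profiles = fit_profiles(disease.dias, stream, annotations, measurements, training)

    reports = []
    for day in all_days[train_days:]:
        dafs = _daily_dafs(disease.dias, stream, tree, measurements, day, window_size)
        gafs = {dia: grade_gaf(dafs[dia], profiles[dia]) for dia in disease.dias}
        dap = build_dap(day, gafs, disease.dias)
        reports.append(daily_risk_series([disease], [dap])[0])

    clean = [r.risk for r in reports if r.day not in set(drift_dates)]
    drift = [r.risk for r in reports if r.day in set(drift_dates)]
    return {
        "clean_risks": clean,
        "drift_risks": drift,
        "reports": reports,
        "profiles": profiles,
        "tree": tree,
    }
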