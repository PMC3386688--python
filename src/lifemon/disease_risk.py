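"""Disease definitions, pattern-distance risk scoring and alerts.

A lifestyle disease is registered as an ordered list of disease-influenced
activities (DIAs) together with a doctor-specified disease pattern: the
GAF vector the disease's early signs would produce (e.g. diabetes —
frequent eating, sleeping, movement and toileting with falling weight —
is encoded (2, 2, 2, 2, -2)).  Each monitored day the daily activity
pattern is compared with the disease pattern by Euclidean distance,
normalized by the maximum attainable distance sqrt((GAF_MAX - GAF_MIN)^2 * n)
so it lies in [0, 1].  The risk score is one minus that normalized
distance; an alert fires when the risk exceeds the definition's threshold.

Both the risk and the raw distance ratio are carried in every report, so
either convention can be audited downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .pattern_stats import GAF_MAX, GAF_MIN, DailyActivityPattern

#: Verbal band name -> GAF grade, accepted in disease-pattern JSON.
NAME_TO_GRADE = {"very low": -2, "low": -1, "regular": 0, "high": 1, "very high": 2}

#: Alert threshold used when a definition does not specify one.
DEFAULT_THRESHOLD = 0.9


class DefinitionError(ValueError):
    """A disease-definition document fails validation."""


@dataclass(frozen=True)
class DiseaseDefinition:
    """A registered disease: its DIA list, disease pattern and alert threshold."""

    name: str
    dias: tuple[str, ...]
    pattern: tuple[int, ...]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.dias:
            raise DefinitionError(f"{self.name!r}: empty DIA list")
        if len(set(self.dias)) != len(self.dias):
            raise DefinitionError(f"{self.name!r}: duplicate DIA")
        if len(self.pattern) != len(self.dias):
            raise DefinitionError(
                f"{self.name!r}: pattern length {len(self.pattern)} != {len(self.dias)} DIAs"
            )
        for entry in self.pattern:
            if not (GAF_MIN <= entry <= GAF_MAX) or int(entry) != entry:
                raise DefinitionError(
                    f"{self.name!r}: pattern entry {entry!r} outside [{GAF_MIN}, {GAF_MAX}]"
                )
        if not (0.0 <= self.threshold <= 1.0):
            raise DefinitionError(f"{self.name!r}: threshold {self.threshold} outside [0, 1]")


@dataclass(frozen=True)
class RiskReport:
    """One day's risk assessment for one disease."""

    day: date
    disease: str
    risk: float
    distance_ratio: float
    alert: bool
    deviations: tuple[tuple[str, int], ...]

    def to_json_dict(self) -> dict:
        return {
            "day": self.day.isoformat() if self.day is not None else None,
            "disease": self.disease,
            "risk": self.risk,
            "distance_ratio": self.distance_ratio,
            "alert": self.alert,
            "deviations": [{"dia": d, "gaf": g} for d, g in self.deviations],
        }


def normalized_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Euclidean distance between two graded vectors, scaled to [0, 1].

    The normalizer is the distance between the all-``GAF_MAX`` and
    all-``GAF_MIN`` vectors, ``sqrt((GAF_MAX - GAF_MIN)^2 * n)``, so the
    result is 0 iff the vectors are equal and 1 iff they disagree
    maximally in every coordinate.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.ndim != 1 or av.shape != bv.shape or av.size == 0:
        raise ValueError("graded vectors must share a common positive length")
    for vec in (av, bv):
        if (vec < GAF_MIN).any() or (vec > GAF_MAX).any():
            raise ValueError(f"graded entries must lie in [{GAF_MIN}, {GAF_MAX}]")
    max_distance = math.sqrt((GAF_MAX - GAF_MIN) ** 2 * av.size)
    return float(np.linalg.norm(av - bv) / max_distance)


def disease_risk(disease: DiseaseDefinition, dap: DailyActivityPattern) -> RiskReport:
    """Score one day against one disease: risk = 1 - normalized distance.

    The daily pattern must cover every DIA of the disease; it is
    restricted and re-ordered to the disease's DIA list before comparison.
    An alert fires when the risk strictly exceeds the threshold.
    """
    missing = [dia for dia in disease.dias if dia not in dap.dia_order]
    if missing:
        raise KeyError(f"daily pattern lacks DIAs required by {disease.name!r}: {missing}")
    day_vector = tuple(dap.gaf(dia) for dia in disease.dias)
    ratio = normalized_distance(disease.pattern, day_vector)
    risk = 1.0 - ratio
    return RiskReport(
        day=dap.day,
        disease=disease.name,
        risk=risk,
        distance_ratio=ratio,
        alert=risk > disease.threshold,
        deviations=tuple((dia, g) for dia, g in zip(disease.dias, day_vector) if g != 0),
    )


def daily_risk_series(
    definitions: Sequence[DiseaseDefinition], daps: Iterable[DailyActivityPattern]
) -> list[RiskReport]:
    """One report per (day, disease), days in the order given."""
    return [disease_risk(d, dap) for dap in daps for d in definitions]


# ---------------------------------------------------------------------------
# JSON loading
# ---------------------------------------------------------------------------

def load_disease_definitions(
    source: str | Path | IO[str] | dict | list,
) -> list[DiseaseDefinition]:
    """Load and validate disease definitions from JSON.

    Accepts a path, an open file, a JSON string, or an already parsed
    document; the document may be a single definition object or a list of
    them.  Pattern entries may be integers or the verbal band names
    ("very low" ... "very high"), which map to -2 ... 2.
    """
    doc = _load_json(source)
    items = doc if isinstance(doc, list) else [doc]
    definitions = []
    for item in items:
        if not isinstance(item, dict):
            raise DefinitionError(f"definition must be a JSON object, got {type(item).__name__}")
        try:
            name = item["name"]
            dias = item["dias"]
            raw_pattern = item["pattern"]
        except KeyError as exc:
            raise DefinitionError(f"definition missing required key {exc.args[0]!r}") from None
        pattern = tuple(_grade(entry, name) for entry in raw_pattern)
        threshold = float(item.get("threshold", DEFAULT_THRESHOLD))
        definitions.append(DiseaseDefinition(name, tuple(dias), pattern, threshold))
    return definitions


def _grade(entry: int | str, disease: str) -> int:
    if isinstance(entry, str):
        try:
            return NAME_TO_GRADE[entry.strip().lower()]
        except KeyError:
            raise DefinitionError(f"{disease!r}: unknown grade name {entry!r}") from None
    if isinstance(entry, bool) or not isinstance(entry, (int, float)):
        raise DefinitionError(f"{disease!r}: pattern entry {entry!r} is not a grade")
    return int(entry)


def _load_json(source: str | Path | IO[str] | dict | list) -> dict | list:
    if isinstance(source, (dict, list)):
        return source
    if isinstance(source, Path):
        return json.loads(source.read_text(encoding="utf-8"))
    if isinstance(source, str):
        stripped = source.lstrip()
        if stripped.startswith("{") or stripped.startswith("["):
            return json.loads(source)
        return json.loads(Path(source).read_text(encoding="utf-8"))
    return json.load(source)


def _packaged(name: str) -> list[DiseaseDefinition]:
    text = resources.files("lifemon").joinpath("data").joinpath(name).read_text(encoding="utf-8")
    return load_disease_definitions(text)


def diabetes_definition() -> DiseaseDefinition:
    """The bundled diabetes registration.

    Five DIAs — eating, sleeping, movement, toileting and weight — with
    the disease pattern (very high, very high, very high, very high,
    very low), i.e. (2, 2, 2, 2, -2).
    """
    return _packaged("diabetes.json")[0]


def depression_definition() -> DiseaseDefinition:
    """The bundled depression registration (synthetic pattern).

    The DIA list (lighting, going out, sleeping, eating, weight) follows
    the usual depression signs — activity in mild illumination, staying
    in, sleep and appetite changes, weight loss — but the grade vector is
    a synthetic stand-in chosen by this package, not a clinically
    validated pattern.
    """
    return _packaged("depression_synthetic.json")[0]


def builtin_definitions() -> list[DiseaseDefinition]:
    """All disease definitions bundled with the package."""
    return [diabetes_definition(), depression_definition()]
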