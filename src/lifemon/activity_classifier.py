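"""Decision-tree activity recognition over binary sensor features.

The classifier follows the C4.5 recipe restricted to binary features:
splits maximize the gain ratio (information gain divided by split
information), each feature is tested at most once per root-to-leaf path,
leaves predict the majority class with ties broken lexicographically, and
an optional pessimistic-error pruning pass collapses subtrees whose
upper-bound error is no better than a single leaf.  Training is fully
deterministic; at equal gain ratio the lowest feature index wins.

Impure nodes are split whenever some remaining feature separates the
samples, even at zero immediate gain, so that feature sets whose classes
are only jointly informative (parity-like co-occurrence patterns) are
still learned exactly; on consistent data with ``min_leaf=1`` the training
error is therefore zero.

Identical duplicate rows are collapsed into weighted counts before
growing the tree, which leaves every entropy, majority and ``min_leaf``
computation unchanged while making training fast on long window streams.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sensor_io import LabeledWindow

#: Normal deviate for the default 25% confidence level of pessimistic pruning.
_Z25 = 0.6744897501960817


@dataclass
class _Node:
    counts: np.ndarray  # weighted class counts of the training samples routed here
    label: int = 0  # majority class index (first maximum = lexicographic winner)
    feature: int | None = None
    low: "_Node | None" = None  # feature value 0
    high: "_Node | None" = None  # feature value 1

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class DecisionTree:
    """A trained tree mapping per-window binary feature vectors to labels."""

    def __init__(self, root: _Node, feature_names: Sequence[str], class_names: Sequence[str]):
        self.root = root
        self.feature_names = list(feature_names)
        self.class_names = list(class_names)

    # -- prediction --------------------------------------------------------

    def _vector(self, features: Mapping[str, int] | Sequence[int]) -> Sequence[int]:
        if isinstance(features, Mapping):
            try:
                return [features[name] for name in self.feature_names]
            except KeyError as exc:
                raise ValueError(f"feature vector lacks sensor {exc.args[0]!r}") from None
        if len(features) != len(self.feature_names):
            raise ValueError(
                f"feature vector has {len(features)} entries, expected {len(self.feature_names)}"
            )
        return features

    def predict(self, features: Mapping[str, int] | Sequence[int]) -> str:
        """Route one binary feature vector to its leaf label (total function)."""
        x = self._vector(features)
        node = self.root
        while not node.is_leaf:
            node = node.high if x[node.feature] else node.low
        return self.class_names[node.label]

    def predict_batch(self, windows: Iterable[LabeledWindow | Mapping[str, int]]) -> list[str]:
        return [
            self.predict(w.features if isinstance(w, LabeledWindow) else w) for w in windows
        ]

    def training_accuracy(self, data: Sequence[LabeledWindow]) -> float:
        hits = sum(self.predict(w.features) == w.label for w in data)
        return hits / len(data)

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        def encode(node: _Node) -> dict:
            counts = {
                self.class_names[i]: float(c) for i, c in enumerate(node.counts) if c > 0
            }
            if node.is_leaf:
                return {"label": self.class_names[node.label], "counts": counts}
            return {
                "feature": self.feature_names[node.feature],
                "counts": counts,
                "children": {"0": encode(node.low), "1": encode(node.high)},
            }

        return {
            "feature_names": self.feature_names,
            "class_names": self.class_names,
            "root": encode(self.root),
        }

    def save(self, dest: str | Path | IO[str]) -> None:
        if isinstance(dest, (str, Path)):
            with open(dest, "w", encoding="utf-8") as handle:
                self.save(handle)
            return
        json.dump(self.to_json_dict(), dest, indent=1, ensure_ascii=False)

    @classmethod
    def from_json_dict(cls, doc: dict) -> "DecisionTree":
        feature_index = {name: i for i, name in enumerate(doc["feature_names"])}
        class_index = {name: i for i, name in enumerate(doc["class_names"])}
        k = len(class_index)

        def decode(obj: dict) -> _Node:
            counts = np.zeros(k)
            for name, c in obj.get("counts", {}).items():
                counts[class_index[name]] = c
            if "feature" in obj:
                node = _Node(counts=counts, feature=feature_index[obj["feature"]])
                node.low = decode(obj["children"]["0"])
                node.high = decode(obj["children"]["1"])
            else:
                node = _Node(counts=counts, label=class_index[obj["label"]])
            node.label = int(np.argmax(counts)) if counts.any() else node.label
            return node

        return cls(decode(doc["root"]), doc["feature_names"], doc["class_names"])

    @classmethod
    def load(cls, source: str | Path | IO[str]) -> "DecisionTree":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as handle:
                return cls.load(handle)
        return cls.from_json_dict(json.load(source))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_tree(
    data: Sequence[LabeledWindow], min_leaf: int = 2, prune: bool = False
) -> DecisionTree:
    """Train a gain-ratio decision tree on labeled windows.

    ``min_leaf`` is the minimum number of training windows each child of a
    split must receive.  With ``prune=True`` a pessimistic-error pass
    collapses splits that do not beat a leaf's upper-bound error estimate.
    """
    data = list(data)
    if not data:
        raise ValueError("empty training set")
    feature_names = list(data[0].features.keys())
    X = np.array([[w.features[f] for f in feature_names] for w in data], dtype=np.uint8)
    labels = [w.label for w in data]
    return train_tree_arrays(X, labels, feature_names, min_leaf=min_leaf, prune=prune)


def train_tree_arrays(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    *,
    min_leaf: int = 2,
    prune: bool = False,
) -> DecisionTree:
    """Array-level training entry point (rows = windows, columns = sensors)."""
    X = np.asarray(X, dtype=np.uint8)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("X must be (n_windows, n_features) matching labels")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    class_names = sorted(set(labels))
    code = {c: i for i, c in enumerate(class_names)}
    y = np.fromiter((code[l] for l in labels), dtype=np.intp, count=len(labels))

    # collapse duplicate (features, label) rows into multiplicities
    stacked = np.column_stack([X, y.astype(np.int64)])
    unique, mult = np.unique(stacked, axis=0, return_counts=True)
    Xu = unique[:, :-1].astype(np.uint8)
    yu = unique[:, -1].astype(np.intp)
    w = mult.astype(float)

    avail = np.ones(X.shape[1], dtype=bool)
    root = _grow(Xu, yu, w, avail, min_leaf, len(class_names))
    if prune:
        _prune(root)
    return DecisionTree(root, feature_names, class_names)


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _grow(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, avail: np.ndarray, min_leaf: int, k: int
) -> _Node:
    counts = np.bincount(y, weights=w, minlength=k)
    node = _Node(counts=counts, label=int(np.argmax(counts)))
    if np.count_nonzero(counts) <= 1 or not avail.any():
        return node

    parent_entropy = _entropy(counts)
    total = w.sum()
    best_ratio = -math.inf
    best_feature = -1
    best_mask: np.ndarray | None = None
    for j in np.flatnonzero(avail):
        hi = X[:, j] == 1
        w_hi = float(w[hi].sum())
        w_lo = total - w_hi
        if w_hi < min_leaf or w_lo < min_leaf:
            continue
        child_entropy = (
            w_lo * _entropy(np.bincount(y[~hi], weights=w[~hi], minlength=k))
            + w_hi * _entropy(np.bincount(y[hi], weights=w[hi], minlength=k))
        ) / total
        gain = parent_entropy - child_entropy
        p_lo = w_lo / total
        split_info = -(p_lo * math.log2(p_lo) + (1 - p_lo) * math.log2(1 - p_lo))
        ratio = gain / split_info
        if ratio > best_ratio + 1e-12:  # strict: lowest index wins ties
            best_ratio, best_feature, best_mask = ratio, int(j), hi

    if best_mask is None:
        return node
    node.feature = best_feature
    child_avail = avail.copy()
    child_avail[best_feature] = False
    lo = ~best_mask
    node.low = _grow(X[lo], y[lo], w[lo], child_avail, min_leaf, k)
    node.high = _grow(X[best_mask], y[best_mask], w[best_mask], child_avail, min_leaf, k)
    return node


def _pessimistic_errors(errors: float, n: float, z: float = _Z25) -> float:
    """Upper confidence bound on the error count of a leaf (C4.5 style)."""
    if n <= 0:
        return 0.0
    f = errors / n
    upper = (f + z * z / (2 * n) + z * math.sqrt(f * (1 - f) / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return upper * n


def _prune(node: _Node) -> float:
    n = float(node.counts.sum())
    leaf_estimate = _pessimistic_errors(n - float(node.counts.max()), n)
    if node.is_leaf:
        return leaf_estimate
    subtree_estimate = _prune(node.low) + _prune(node.high)
    if leaf_estimate <= subtree_estimate + 0.1:  # collapse on ties, as C4.5 does
        node.feature = None
        node.low = node.high = None
        return leaf_estimate
    return subtree_estimate


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Leave-one-day-out evaluation summary.

    ``confusion`` rows are true labels, columns predicted labels;
    ``accuracy`` equals the trace over the grand total.
    """

    accuracy: float
    confusion: pd.DataFrame
    window_size: int | None
    folds: int
    fold_results: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "window_size": self.window_size,
            "folds": self.folds,
            "fold_results": self.fold_results,
            "labels": list(self.confusion.index),
            "confusion": self.confusion.to_numpy().tolist(),
        }


def leave_one_day_out(
    data: Sequence[LabeledWindow],
    window_size: int | None = None,
    *,
    min_leaf: int = 2,
    prune: bool = False,
) -> EvalReport:
    """Hold out all windows of one calendar day per fold and aggregate.

    Accuracy is the fraction of held-out windows whose predicted label
    matches the annotation (time-slice accuracy), pooled over all folds.
    """
    data = list(data)
    days = sorted({w.day for w in data})
    if len(days) < 2:
        raise ValueError("leave-one-day-out needs at least two distinct days")
    if window_size is None:
        window_size = data[0].window_size
    labels = sorted({w.label for w in data})
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    fold_results = []
    for day in days:
        train = [w for w in data if w.day != day]
        held_out = [w for w in data if w.day == day]
        tree = train_tree(train, min_leaf=min_leaf, prune=prune)
        correct = 0
        for window in held_out:
            predicted = tree.predict(window.features)
            confusion.loc[window.label, predicted] += 1
            correct += predicted == window.label
        fold_results.append({"day": day.isoformat(), "n": len(held_out), "correct": correct})
    total = int(confusion.to_numpy().sum())
    accuracy = float(np.trace(confusion.to_numpy()) / total)
    return EvalReport(accuracy, confusion, window_size, len(days), fold_results)
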