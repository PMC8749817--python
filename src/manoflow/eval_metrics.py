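"""Confusion-matrix evaluation with per-class precision/recall/F1.

Metrics follow the usual binary-classification definitions computed per
class from the 2x2 confusion matrix (rows = true class, columns =
predicted class): precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = the
harmonic mean of the two, accuracy = trace/total.  Values are kept at full
precision internally and expressed as percentages; for display they are
rounded half-up to whole percent, matching the usual reporting convention.

A metric with a zero denominator is reported as 0 and flagged rather than
propagated as NaN.  The positive class is task-dependent (correct catheter
positioning for the positioning task; normal IRP for the IRP task) and is
recorded in the report rather than changing the per-class numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """2-class confusion counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: Tuple[str, str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.class_names),) * 2:
            raise ValueError("counts must be square over class_names")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    precision: float  # percent
    recall: float
    f1: float
    zero_denominator_flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class EvalReport:
    confusion: ConfusionMatrix
    positive_class: str
    accuracy: float  # percent, full precision
    per_class: Dict[str, ClassMetrics]

    def display(self) -> dict:
        """Whole-percent, half-up-rounded view of the report."""
        return {
            "positive_class": self.positive_class,
            "accuracy": round_half_up(self.accuracy),
            "per_class": {
                name: {
                    "precision": round_half_up(m.precision),
                    "recall": round_half_up(m.recall),
                    "f1": round_half_up(m.f1),
                }
                for name, m in self.per_class.items()
            },
        }

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "accuracy": self.accuracy,
            "confusion": self.confusion.counts.tolist(),
            "class_names": list(self.confusion.class_names),
            "per_class": {
                name: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "zero_denominator_flags": list(m.zero_denominator_flags),
                }
                for name, m in self.per_class.items()
            },
        }


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-to-up."""
    return int(math.floor(x + 0.5))


def confusion(
    truths: Sequence[str], predictions: Sequence[str], class_names: Sequence[str]
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into a confusion matrix."""
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions must have equal length")
    names = tuple(class_names)
    index = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for t, p in zip(truths, predictions):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) not in {names}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=names)  # type: ignore[arg-type]


def f1_from_pair(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of a precision/recall pair, in percent."""
    if precision_pct <= 0 and recall_pct <= 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def report(cm: ConfusionMatrix, positive_class: str) -> EvalReport:
    """Per-class precision/recall/F1 and overall accuracy from a matrix."""
    if cm.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")
    if positive_class not in cm.class_names:
        raise ValueError(
            f"positive class {positive_class!r} not among {cm.class_names}"
        )
    per_class: Dict[str, ClassMetrics] = {}
    for i, name in enumerate(cm.class_names):
        tp = float(cm.counts[i, i])
        fp = float(cm.counts[:, i].sum() - tp)
        fn = float(cm.counts[i, :].sum() - tp)
        flags: List[str] = []
        if tp + fp > 0:
            precision = 100.0 * tp / (tp + fp)
        else:
            precision, _ = 0.0, flags.append("precision")
        if tp + fn > 0:
            recall = 100.0 * tp / (tp + fn)
        else:
            recall, _ = 0.0, flags.append("recall")
        if precision + recall > 0:
            f1 = f1_from_pair(precision, recall)
        else:
            f1, _ = 0.0, flags.append("f1")
        per_class[name] = ClassMetrics(
            precision=precision, recall=recall, f1=f1,
            zero_denominator_flags=tuple(flags),
        )
    accuracy = 100.0 * float(np.trace(cm.counts)) / cm.total
    return EvalReport(
        confusion=cm, positive_class=positive_class,
        accuracy=accuracy, per_class=per_class,
    )
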