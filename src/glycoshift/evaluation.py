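"""Confusion-matrix metrics with the study's reporting conventions.

Per class, *sensitivity* is TP / (TP + FN).  *Specificity* is reported
here as TP / (TP + FP) — what is conventionally called precision; this
nonstandard usage is kept because the reported tables are defined with
it, and the TN-based conventional quantity is available separately as
:func:`specificity_standard`.  The summary statistic *mean
predictability* is the unweighted mean of per-class sensitivities over
all non-empty classes — including a not-applicable ``X`` class when the
task has one — expressed as a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import TASKS

__all__ = [
    "ConfusionMatrix",
    "TaskReport",
    "sensitivity",
    "specificity_paper",
    "specificity_standard",
    "mean_predictability",
    "evaluate",
    "compare",
]


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); undefined (None) for an empty class."""
    if tp < 0 or fn < 0:
        raise ValueError("negative counts")
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def specificity_paper(tp: int, fp: int) -> float:
    """TP / (TP + FP), i.e. precision; undefined (None) without positive predictions."""
    if tp < 0 or fp < 0:
        raise ValueError("negative counts")
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def specificity_standard(tn: int, fp: int) -> float:
    """The conventional TN-based specificity TN / (TN + FP)."""
    if tn < 0 or fp < 0:
        raise ValueError("negative counts")
    if tn + fp == 0:
        return None
    return tn / (tn + fp)


@dataclass
class ConfusionMatrix:
    """True-class x predicted-class tallies over a fixed class alphabet."""

    task: str
    classes: list[str]
    counts: np.ndarray  # (k, k), rows = true class

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a square matrix over the class alphabet")
        if np.any(self.counts < 0):
            raise ValueError("negative confusion counts")

    @classmethod
    def from_labels(cls, task: str, classes: Sequence[str], y_true: Sequence[str], y_pred: Sequence[str]) -> "ConfusionMatrix":
        classes = list(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(task=task, classes=classes, counts=counts)

    @classmethod
    def from_class_counts(cls, task: str, pairs: Mapping[str, tuple[int, int]]) -> "ConfusionMatrix":
        """Build a diagonal-vs-rest matrix from per-class (size, correct) pairs.

        Misclassified objects are spread over an artificial off-diagonal
        cell; only row-wise quantities (sizes, sensitivities, mean
        predictability) are meaningful on the result.
        """
        classes = list(pairs)
        k = len(classes)
        counts = np.zeros((k, k), dtype=np.int64)
        for i, (size, correct) in enumerate(pairs.values()):
            if correct > size:
                raise ValueError(f"class {classes[i]}: correct {correct} exceeds size {size}")
            counts[i, i] = correct
            if size > correct:
                if k == 1:
                    raise ValueError(
                        "cannot represent misclassifications with a single class"
                    )
                counts[i, (i + 1) % k] += size - correct
        return cls(task=task, classes=classes, counts=counts)

    @property
    def sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def correct(self) -> np.ndarray:
        return np.diag(self.counts)


def mean_predictability(cm: ConfusionMatrix) -> float:
    """100 x unweighted mean of per-class sensitivities over non-empty classes."""
    sizes = cm.sizes
    if not np.any(sizes > 0):
        raise ValueError("all classes are empty")
    present = sizes > 0
    sens = cm.correct[present] / sizes[present]
    return float(100.0 * np.mean(sens))


@dataclass
class TaskReport:
    """Per-class sizes, correct counts and metrics plus the task summary."""

    task: str
    classes: list[str]
    sizes: list[int]
    correct: list[int]
    sensitivity: list[float | None]
    specificity: list[float | None]
    mean_predictability: float
    confusion: ConfusionMatrix | None = field(default=None, repr=False)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "TaskReport":
        sizes = cm.sizes
        predicted = cm.counts.sum(axis=0)
        sens = [sensitivity(int(tp), int(sz - tp)) for tp, sz in zip(cm.correct, sizes)]
        spec = [specificity_paper(int(tp), int(pp - tp)) for tp, pp in zip(cm.correct, predicted)]
        return cls(
            task=cm.task,
            classes=list(cm.classes),
            sizes=[int(v) for v in sizes],
            correct=[int(v) for v in cm.correct],
            sensitivity=sens,
            specificity=spec,
            mean_predictability=mean_predictability(cm),
            confusion=cm,
        )

    def to_frame(self) -> pd.DataFrame:
        def fmt(v):
            return "---" if v is None else round(v, 4)

        return pd.DataFrame(
            {
                "task": self.task,
                "class": self.classes,
                "size": self.sizes,
                "correct": self.correct,
                "sensitivity": [fmt(v) for v in self.sensitivity],
                "specificity": [fmt(v) for v in self.specificity],
                "mean_predictability": round(self.mean_predictability, 2),
            }
        )


def evaluate(
    y_true: pd.DataFrame,
    y_pred: pd.DataFrame,
    tasks: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, TaskReport]:
    """One confusion matrix + report per task from aligned label tables."""
    tasks = tasks or {t: TASKS[t] for t in y_true.columns if t in TASKS}
    missing = y_true.index[y_true.isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"records without true labels: {missing}")
    reports = {}
    for task, alphabet in tasks.items():
        cm = ConfusionMatrix.from_labels(task, alphabet, list(y_true[task]), list(y_pred[task]))
        reports[task] = TaskReport.from_confusion(cm)
    return reports


def reports_frame(reports: Mapping[str, TaskReport]) -> pd.DataFrame:
    return pd.concat([r.to_frame() for r in reports.values()], ignore_index=True)


def compare(report_sets: Mapping[str, Mapping[str, Mapping[str, TaskReport]]]) -> pd.DataFrame:
    """Mean-predictability comparison table.

    ``report_sets`` maps method name -> {"internal"/"test" -> {task ->
    TaskReport}}; the result has one row per task and one column per
    (evaluation set, method), mirroring the usual method-comparison
    layout.
    """
    columns = {}
    tasks: list[str] = []
    for method, by_set in report_sets.items():
        for set_name, reports in by_set.items():
            col = {task: round(rep.mean_predictability, 2) for task, rep in reports.items()}
            columns[(set_name, method)] = col
            for task in reports:
                if task not in tasks:
                    tasks.append(task)
    frame = pd.DataFrame(index=tasks, columns=pd.MultiIndex.from_tuples(columns.keys()))
    for key, col in columns.items():
        for task, value in col.items():
            frame.loc[task, key] = value
    return frame
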