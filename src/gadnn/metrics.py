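"""Evaluation reports: confusion-matrix metrics and regression error.

Classification is scored per class, one-vs-rest: precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), with overall accuracy the trace of the
multi-class confusion matrix over the total count.  Regression is scored by
RMSE and the coefficient of determination R² = 1 − SS_res/SS_tot.  Ratios
with a zero denominator are reported as 0.0 and flagged rather than NaN, so
reports stay serializable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    tp: int
    tn: int
    fp: int
    fn: int
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class EvalReport:
    """Per-class precision/recall/F1 plus overall accuracy."""

    classes: tuple[str, ...]
    per_class: dict[str, ClassMetrics]
    accuracy: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        """One row per class plus an overall accuracy row."""
        rows = []
        for c in self.classes:
            m = self.per_class[c]
            rows.append(
                {"class": c, "precision": m.precision, "recall": m.recall,
                 "f1": m.f1, "support": m.support, "accuracy": np.nan}
            )
        rows.append({"class": "overall", "precision": np.nan, "recall": np.nan,
                     "f1": np.nan, "support": self.n, "accuracy": self.accuracy})
        return pd.DataFrame(rows)

    def macro(self) -> dict[str, float]:
        """Unweighted class averages (not part of the default report)."""
        ms = [self.per_class[c] for c in self.classes]
        return {
            "precision": float(np.mean([m.precision for m in ms])),
            "recall": float(np.mean([m.recall for m in ms])),
            "f1": float(np.mean([m.f1 for m in ms])),
        }


@dataclass(frozen=True)
class RegressionReport:
    """RMSE in target units and R²; flags mark degenerate denominators."""

    rmse: float
    r2: float
    n: int
    undefined: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"rmse": self.rmse, "r2": self.r2, "n": self.n}])


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def classification_report(
    truth: Sequence, predicted: Sequence, classes: Sequence | None = None
) -> EvalReport:
    """Score predicted labels against truth, per class and overall.

    ``classes`` fixes the class order of the report; by default the sorted
    union of observed labels is used.  Truth and prediction must have equal
    length, and every label must belong to the class set.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("truth and predicted must be 1-d arrays of equal length")
    if truth.size == 0:
        raise ValueError("empty input")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    classes = tuple(str(c) for c in classes)
    truth = truth.astype(str)
    predicted = predicted.astype(str)
    unseen = (set(truth) | set(predicted)) - set(classes)
    if unseen:
        raise ValueError(f"label(s) outside class set: {sorted(unseen)}")

    n = truth.size
    per_class: dict[str, ClassMetrics] = {}
    for c in classes:
        t_pos = truth == c
        p_pos = predicted == c
        tp = int(np.sum(t_pos & p_pos))
        fp = int(np.sum(~t_pos & p_pos))
        fn = int(np.sum(t_pos & ~p_pos))
        tn = n - tp - fp - fn
        flags: list[str] = []
        precision = _safe_div(tp, tp + fp, "precision", flags)
        recall = _safe_div(tp, tp + fn, "recall", flags)
        f1 = _safe_div(2 * precision * recall, precision + recall, "f1", flags)
        per_class[c] = ClassMetrics(
            precision=precision, recall=recall, f1=f1, support=int(t_pos.sum()),
            tp=tp, tn=tn, fp=fp, fn=fn, undefined=tuple(flags),
        )
    accuracy = float(np.sum(truth == predicted) / n)
    return EvalReport(classes=classes, per_class=per_class, accuracy=accuracy, n=n)


def regression_report(truth: Sequence[float], predicted: Sequence[float]) -> RegressionReport:
    """RMSE and R² of predictions against a continuous truth vector."""
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("truth and predicted must be 1-d arrays of equal length")
    if truth.size == 0:
        raise ValueError("empty input")
    resid = truth - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    flags: list[str] = []
    if ss_tot == 0.0:
        flags.append("r2")
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return RegressionReport(rmse=rmse, r2=float(r2), n=truth.size, undefined=tuple(flags))
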