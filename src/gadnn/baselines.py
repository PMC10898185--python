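"""Comparison models: logistic regression, random forest, the 150-100-50
perceptron, and the plain deep network without GA selection.

Baselines run through the identical preprocessing and evaluation path as the
GA-selected network — same split, same scaler, same metrics — but always see
the full 12-feature set (no mask) and take labels directly (no one-hot of
inputs).  In the continuous-age scenario the "logistic regression" slot is
ordinary least-squares linear regression, since logistic regression is not
defined for a continuous outcome; the naming is kept for the comparison
table only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .metrics import EvalReport, RegressionReport, classification_report, regression_report
from .network import DNNClassifier, DNNRegressor
from .preprocess import SplitDataset, minmax_normalize

logger = logging.getLogger(__name__)

KINDS = ("logistic_regression", "random_forest", "mlp", "deep_learning")

MLP_HIDDEN = (150, 100, 50)


@dataclass(frozen=True)
class BaselineSpec:
    """One comparison model: its family, extra hyperparameters, and seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")


def _build(spec: BaselineSpec, task: str):
    hp = dict(spec.hyperparameters)
    regression = task == "age_regression"
    if spec.kind == "logistic_regression":
        if regression:
            logger.info(
                "continuous-age scenario: the logistic-regression slot is "
                "fit as ordinary linear regression"
            )
            return LinearRegression(**hp)
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.kind == "random_forest":
        cls = RandomForestRegressor if regression else RandomForestClassifier
        return cls(random_state=spec.seed, **hp)
    if spec.kind == "mlp":
        hp.setdefault("hidden_layer_sizes", MLP_HIDDEN)
        hp.setdefault("activation", "relu")
        hp.setdefault("max_iter", 500)
        cls = MLPRegressor if regression else MLPClassifier
        return cls(random_state=spec.seed, **hp)
    # the plain deep network, no GA mask
    if regression:
        return DNNRegressor(random_state=spec.seed, **hp)
    return DNNClassifier(random_state=spec.seed, **hp)


def run_baseline(
    spec: BaselineSpec, split: SplitDataset, task: str
) -> EvalReport | RegressionReport:
    """Fit one baseline on the split's train partition, score on test."""
    Xtr, Xte, _ = minmax_normalize(split.train.features, split.test.features)
    ytr = split.train.labels(task)
    yte = split.test.labels(task)
    model = _build(spec, task)
    if task == "age_regression":
        model.fit(Xtr, ytr.astype(float))
        return regression_report(yte.astype(float), model.predict(Xte))
    model.fit(Xtr, ytr)
    return classification_report(yte, model.predict(Xte),
                                 classes=sorted(set(ytr) | set(yte)))


def compare_models(
    specs: Sequence[BaselineSpec], split: SplitDataset, task: str
) -> pd.DataFrame:
    """Run every spec on the identical split; one ranked row per model.

    Classification ranks by accuracy (ties by macro F1), regression by RMSE
    ascending (ties by R²).  Hyperparameters actually used are echoed for
    audit.
    """
    if len(specs) < 2:
        raise ValueError("a comparison needs at least two models")
    rows = []
    for spec in specs:
        report = run_baseline(spec, split, task)
        row: dict = {"model": spec.kind, "seed": spec.seed,
                     "hyperparameters": repr(spec.hyperparameters)}
        if isinstance(report, RegressionReport):
            row.update(rmse=report.rmse, r2=report.r2)
        else:
            row.update(accuracy=report.accuracy, **{
                f"f1_{c}": report.per_class[c].f1 for c in report.classes})
            row["macro_f1"] = report.macro()["f1"]
        rows.append(row)
    table = pd.DataFrame(rows)
    if task == "age_regression":
        table = table.sort_values(["rmse", "r2"], ascending=[True, False])
    else:
        table = table.sort_values(["accuracy", "macro_f1"], ascending=False)
    return table.reset_index(drop=True)
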