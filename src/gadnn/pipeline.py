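"""End-to-end runs: balance → split → scale → (select) → train → evaluate.

Each run returns its report together with a :class:`RunManifest` capturing
every knob and seed that influenced it plus a digest of the input cohort.
``replay`` re-executes a manifest against the same cohort and verifies that
the reports agree bit for bit — the package's reproducibility contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from .data import Dataset, write_csv
from .metrics import EvalReport, RegressionReport, classification_report, regression_report
from .network import DNNClassifier, DNNRegressor, TrainConfig
from .selection import GAConfig, GadnnResult, _prepare, gadnn_select

TASKS = ("sex", "age_class", "age_regression")


@dataclass
class PipelineConfig:
    """Everything one run depends on besides the cohort itself."""

    task: str = "sex"
    seed: int = 0
    test_fraction: float = 0.2
    use_smote: bool = True
    smote_order: str = "paper"  # "paper": balance before split; "safe": after
    smote_k: int = 5
    use_ga: bool = False
    ga: GAConfig = field(default_factory=GAConfig)
    net: TrainConfig = field(default_factory=TrainConfig)
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["ga"] = GAConfig(**d["ga"])
        d["net"] = TrainConfig(**d["net"])
        return cls(**d)


@dataclass
class RunManifest:
    """A complete, replayable record of one pipeline run."""

    task: str
    config: dict
    input_digest: str
    n_rows: int
    selected: list[str] | None
    report: dict
    wall_time_s: float
    ga_history: list[float] | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def dataset_digest(data: Dataset) -> str:
    """SHA-256 of the canonical CSV serialization of a cohort."""
    buf = io.StringIO()
    from .data import FEATURES
    cols = ["id", "sex", "age", *FEATURES, "synthetic_flag"]
    data.frame[cols].to_csv(buf, index=False, float_format="%.17g")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def report_to_dict(report: EvalReport | RegressionReport) -> dict:
    if isinstance(report, RegressionReport):
        return {"kind": "regression", "rmse": report.rmse, "r2": report.r2,
                "n": report.n, "undefined": list(report.undefined)}
    return {
        "kind": "classification",
        "accuracy": report.accuracy,
        "n": report.n,
        "classes": list(report.classes),
        "per_class": {
            c: {"precision": m.precision, "recall": m.recall, "f1": m.f1,
                "support": m.support}
            for c, m in report.per_class.items()
        },
    }


def _run(data: Dataset, cfg: PipelineConfig):
    t0 = time.perf_counter()
    selected: list[str] | None = None
    ga_history: list[float] | None = None
    if cfg.use_ga:
        ga_cfg = dataclasses.replace(cfg.ga, seed=cfg.seed)
        net_cfg = dataclasses.replace(cfg.net, seed=cfg.seed)
        result: GadnnResult = gadnn_select(
            data, cfg.task, ga_cfg=ga_cfg, net_cfg=net_cfg,
            test_fraction=cfg.test_fraction, smote_order=cfg.smote_order,
            use_smote=cfg.use_smote, dropout=cfg.dropout,
        )
        report = result.report
        selected = list(result.selected)
        ga_history = [float(h) for h in result.history]
    else:
        _, Xtr, ytr, Xte, yte, _ = _prepare(
            data, cfg.task, cfg.test_fraction, cfg.seed,
            cfg.smote_order, cfg.use_smote, cfg.smote_k)
        if cfg.task == "age_regression":
            model = DNNRegressor(epochs=cfg.net.epochs,
                                 batch_size=cfg.net.batch_size,
                                 learning_rate=cfg.net.learning_rate,
                                 dropout=cfg.dropout, random_state=cfg.seed)
            model.fit(Xtr, ytr.astype(float))
            report = regression_report(yte.astype(float), model.predict(Xte))
        else:
            model = DNNClassifier(epochs=cfg.net.epochs,
                                  batch_size=cfg.net.batch_size,
                                  learning_rate=cfg.net.learning_rate,
                                  loss=cfg.net.loss, dropout=cfg.dropout,
                                  random_state=cfg.seed)
            model.fit(Xtr, ytr)
            report = classification_report(
                yte, model.predict(Xte), classes=sorted(set(ytr) | set(yte)))
    manifest = RunManifest(
        task=cfg.task,
        config=cfg.to_dict(),
        input_digest=dataset_digest(data),
        n_rows=len(data),
        selected=selected,
        report=report_to_dict(report),
        wall_time_s=time.perf_counter() - t0,
        ga_history=ga_history,
    )
    return report, manifest


def run_sex_pipeline(data: Dataset, cfg: PipelineConfig | None = None):
    """Balance sexes (SMOTE) → split → scale → (GA) → deep net → report."""
    cfg = dataclasses.replace(cfg or PipelineConfig(), task="sex")
    return _run(data, cfg)


def run_age_classification(data: Dataset, cfg: PipelineConfig | None = None):
    """Bin ages into 4 groups, balance, split, scale, train and report."""
    cfg = dataclasses.replace(cfg or PipelineConfig(), task="age_class")
    return _run(data, cfg)


def run_age_regression(data: Dataset, cfg: PipelineConfig | None = None):
    """Continuous-age run: split, scale, train the regression head; no SMOTE."""
    cfg = dataclasses.replace(cfg or PipelineConfig(), task="age_regression")
    return _run(data, cfg)


def replay(manifest: RunManifest, data: Dataset):
    """Re-run a manifest on its cohort; raises if anything fails to match."""
    digest = dataset_digest(data)
    if digest != manifest.input_digest:
        raise ValueError("cohort does not match the manifest's input digest")
    cfg = PipelineConfig.from_dict(manifest.config)
    report, new_manifest = _run(data, cfg)
    if new_manifest.report != manifest.report:
        raise AssertionError("replayed report differs from the manifest")
    return report, new_manifest
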