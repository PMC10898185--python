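"""Class balancing, scaling, encoding and splitting.

SMOTE here is balance-to-majority: every class is oversampled until it
matches the largest class.  A synthetic point is x + u·(x_nn − x) for a real
class member x, one of its k nearest same-class neighbours x_nn (Euclidean
distance in raw feature space, since balancing precedes normalization in the
default pipeline order) and u uniform on [0, 1] — an exact convex
combination of two real points, which the tests verify against a brute-force
neighbour scan.  Original rows are never modified or dropped; synthetic rows
carry ``synthetic_flag=True``.

Two pipeline orders are supported.  ``paper`` balances the whole cohort and
splits afterwards, which leaks synthetic neighbours of test points into
training; ``safe`` splits first and balances the training partition only.
The safe order is the methodologically sound one and is recommended in the
docs; the paper order is the default because it reproduces the published
procedure.  Min–max scaling is always fitted on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .data import FEATURES, Dataset

__all__ = [
    "SmoteConfig", "Scaler", "SplitDataset",
    "smote_balance", "minmax_normalize", "one_hot", "decode", "split",
]


@dataclass(frozen=True)
class SmoteConfig:
    """k-nearest-neighbour count and seed for balance-to-majority SMOTE."""

    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")


def smote_balance(
    data: Dataset, labels: Sequence, cfg: SmoteConfig = SmoteConfig()
) -> tuple[Dataset, np.ndarray]:
    """Oversample every class up to the size of the largest class.

    Returns the augmented Dataset (original rows first, unchanged, then the
    synthetic rows) and the label vector aligned with it.  Ages of synthetic
    rows are interpolated with the same mixing weight as the features, so a
    row stays coherent (and stays inside its closed age bin when the labels
    are age groups); sex is copied from the seed point when it is not itself
    the class label.
    """
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("one label per row required")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 1):
        raise ValueError("empty class")
    target = int(counts.max())
    rng = np.random.default_rng(cfg.seed)

    X = data.features
    age = data.age
    new_frames: list[pd.DataFrame] = []
    new_labels: list = []
    for c, count in zip(classes, counts):
        need = target - int(count)
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {c!r} has a single member; SMOTE needs a neighbour"
            )
        k = cfg.k
        if k >= count:
            k = int(count) - 1
            warnings.warn(
                f"class {c!r} has {count} members; reducing SMOTE k to {k}",
                stacklevel=2,
            )
        members = np.flatnonzero(labels == c)
        Xc = X[members]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        # column 0 is the point itself; keep the k true neighbours
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]

        seeds = rng.integers(0, len(members), size=need)
        picks = rng.integers(0, k, size=need)
        u = rng.random(need)
        base = Xc[seeds]
        partner = Xc[neigh[seeds, picks]]
        X_new = base + u[:, None] * (partner - base)
        age_new = age[members][seeds] + u * (age[members][neigh[seeds, picks]]
                                             - age[members][seeds])
        frame = pd.DataFrame(X_new, columns=list(FEATURES))
        frame.insert(0, "age", age_new)
        if set(map(str, classes)) <= {"F", "M"}:
            sex_new = np.full(need, c)  # the class label is sex itself
        else:
            sex_new = np.asarray(data.sex)[members][seeds]
        frame.insert(0, "sex", sex_new)
        frame["synthetic_flag"] = True
        new_frames.append(frame)
        new_labels.extend([c] * need)

    if not new_frames:
        return data, labels
    out = pd.concat([data.frame, *new_frames], ignore_index=True)
    out["id"] = np.arange(len(out))
    return Dataset(out), np.concatenate([labels, np.asarray(new_labels)])


@dataclass(frozen=True)
class Scaler:
    """Per-feature min–max bounds fitted on training rows only."""

    data_min_: np.ndarray
    data_max_: np.ndarray

    @property
    def range_(self) -> np.ndarray:
        return self.data_max_ - self.data_min_

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(x − min)/(max − min); constant features map to 0, no clipping."""
        rng = self.range_.copy()
        rng[rng == 0] = 1.0
        return (np.asarray(X, dtype=float) - self.data_min_) / rng

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        rng = self.range_.copy()
        rng[rng == 0] = 1.0
        return np.asarray(X, dtype=float) * rng + self.data_min_


def minmax_normalize(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, Scaler]:
    """Fit min–max bounds on the training matrix and scale both partitions.

    Test values outside the training range fall outside [0, 1]; they are
    deliberately not clipped.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("train must be a non-empty 2-d matrix")
    scaler = Scaler(data_min_=train.min(axis=0), data_max_=train.max(axis=0))
    train_s = scaler.transform(train)
    test_s = scaler.transform(test) if test is not None else None
    return train_s, test_s, scaler


def one_hot(labels: Sequence, classes: Sequence) -> np.ndarray:
    """Binary indicator matrix; exactly one 1 per row."""
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    unseen = set(labels) - set(classes)
    if unseen:
        raise ValueError(f"label(s) not in class set: {sorted(map(str, unseen))}")
    return (labels[:, None] == classes[None, :]).astype(float)


def decode(scores: np.ndarray, classes: Sequence) -> np.ndarray:
    """Argmax decoding; ties break toward the lowest class index."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    classes = np.asarray(classes)
    if scores.shape[1] != len(classes):
        raise ValueError("one score column per class required")
    return classes[np.argmax(scores, axis=1)]


@dataclass
class SplitDataset:
    """A train/test partition with its provenance."""

    train: Dataset
    test: Dataset
    test_fraction: float
    seed: int
    smote_order: str = "paper"  # or "safe"

    def __post_init__(self) -> None:
        if self.smote_order not in ("paper", "safe"):
            raise ValueError("smote_order must be 'paper' or 'safe'")


def split(
    data: Dataset,
    labels: Sequence | None,
    test_fraction: float = 0.2,
    seed: int = 0,
    smote_order: str = "paper",
) -> SplitDataset:
    """Seeded split, stratified by ``labels`` when given (classification),
    plain random otherwise (regression)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if labels is not None:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("every stratum needs at least 2 rows to be split")
    idx_train, idx_test = train_test_split(
        np.arange(len(data)),
        test_size=test_fraction,
        random_state=seed,
        stratify=labels,
    )
    return SplitDataset(
        train=data.subset(np.sort(idx_train)),
        test=data.subset(np.sort(idx_test)),
        test_fraction=test_fraction,
        seed=seed,
        smote_order=smote_order,
    )
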