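"""Domain model for sinus-morphometry cohorts.

One subject contributes twelve strictly positive measurements — length,
width, height and volume of the frontal sinus and of each maxillary sinus —
plus sex and age in years.  The feature order below is canonical across the
whole package: binary feature masks used by the genetic-algorithm selector
index into it, so it must never be permuted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical feature order: frontal block, right maxillary block, left
#: maxillary block.  Bit i of a FeatureMask refers to FEATURES[i].
FEATURES: tuple[str, ...] = (
    "FSL", "FSW", "FSH", "FSV",
    "RMSL", "RMSW", "RMSH", "RMSV",
    "LMSL", "LMSW", "LMSH", "LMSV",
)

#: Columns measured in mm³ (the rest are mm).
VOLUME_FEATURES: tuple[str, ...] = ("FSV", "RMSV", "LMSV")

SEX_LEVELS: tuple[str, str] = ("F", "M")

_REQUIRED_COLUMNS = ("sex", "age") + FEATURES


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. non-positive measurement)."""


class AgeOutOfRangeError(ValueError):
    """Age below the cohort's lower bound of 18 years."""


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, contiguous, closed age bins with unique labels.

    The default four groups A:[18,25], B:[26,33], C:[34,41], D:[42,50]
    partition the cohort's age range into 8-year classes.  With
    ``clamp_above`` (the default), ages above the top bin map into the last
    group with a logged warning instead of raising, so slightly older
    subjects remain ingestible.
    """

    bins: tuple[tuple[int, int], ...] = ((18, 25), (26, 33), (34, 41), (42, 50))
    labels: tuple[str, ...] = ("A", "B", "C", "D")
    clamp_above: bool = True

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.labels):
            raise ValueError("one label per bin required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        for (lo, hi) in self.bins:
            if hi < lo:
                raise ValueError(f"bin [{lo}, {hi}] is empty")
        for (_, hi), (lo2, _) in zip(self.bins, self.bins[1:]):
            if lo2 != hi + 1:
                raise ValueError("bins must be contiguous, ordered and non-overlapping")

    @property
    def lower(self) -> int:
        return self.bins[0][0]

    @property
    def upper(self) -> int:
        return self.bins[-1][1]


DEFAULT_AGE_SCHEME = AgeGroupScheme()


def bin_age(
    age: float, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME, warn: bool = True
) -> str:
    """Map an age in years to its group label.

    Total, monotone step function on [lower, ∞).  Ages above the top bin
    return the last label with a warning when ``scheme.clamp_above`` is set,
    otherwise raise.  Ages below the lower bound always raise: the cohort is
    defined on adults with completed sinus development.
    """
    if age < scheme.lower:
        raise AgeOutOfRangeError(
            f"age {age} below cohort minimum of {scheme.lower} years"
        )
    # Bins are printed as closed integer intervals; on real-valued ages each
    # bin extends up to (not including) the next bin's lower bound, so the
    # mapping is total and monotone on [lower, upper].
    for (lo, hi), next_bin, label in zip(
        scheme.bins, scheme.bins[1:] + (None,), scheme.labels
    ):
        if next_bin is not None and age < next_bin[0]:
            return label
        if next_bin is None and age <= hi:
            return label
    if scheme.clamp_above:
        if warn:
            logger.warning(
                "age %s above top bin [%s, %s]; clamped into group %s",
                age, scheme.bins[-1][0], scheme.bins[-1][1], scheme.labels[-1],
            )
        return scheme.labels[-1]
    raise AgeOutOfRangeError(f"age {age} above top bin and clamp_above is False")


@dataclass
class Dataset:
    """A cohort as a validated DataFrame plus bookkeeping.

    Columns: ``id``, ``sex`` ("F"/"M"), ``age`` (years), the twelve
    measurements in canonical order, and ``synthetic_flag`` marking rows
    created by SMOTE or the simulator.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in _REQUIRED_COLUMNS if c not in f.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if "id" not in f.columns:
            f = f.copy()
            f.insert(0, "id", np.arange(len(f)))
        if "synthetic_flag" not in f.columns:
            f = f.copy()
            f["synthetic_flag"] = False
        f = f.reset_index(drop=True)
        bad_sex = ~f["sex"].isin(SEX_LEVELS)
        if bad_sex.any():
            raise ValidationError(
                f"row {int(np.flatnonzero(bad_sex)[0])}: sex must be one of {SEX_LEVELS}"
            )
        for col in FEATURES:
            vals = pd.to_numeric(f[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(
                    f"row {int(np.flatnonzero(vals.isna())[0])}: "
                    f"non-numeric value in column {col}"
                )
            nonpos = vals <= 0
            if nonpos.any():
                raise ValidationError(
                    f"row {int(np.flatnonzero(nonpos)[0])}: "
                    f"{col} must be strictly positive"
                )
            f[col] = vals.astype(float)
        ages = pd.to_numeric(f["age"], errors="coerce")
        if ages.isna().any() or (ages < 0).any():
            raise ValidationError("age must be numeric and non-negative")
        f["age"] = ages.astype(float)
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> np.ndarray:
        """(n, 12) measurement matrix in canonical feature order."""
        return self.frame[list(FEATURES)].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.frame["sex"].to_numpy()

    @property
    def age(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def synthetic_flag(self) -> np.ndarray:
        return self.frame["synthetic_flag"].to_numpy(dtype=bool)

    def age_groups(self, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME) -> np.ndarray:
        labels = np.array([bin_age(a, scheme, warn=False) for a in self.age])
        n_clamped = int(np.sum(self.age > scheme.upper))
        if n_clamped and scheme.clamp_above:
            logger.warning(
                "%d age(s) above top bin clamped into group %s",
                n_clamped, scheme.labels[-1],
            )
        return labels

    def labels(self, task: str, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME) -> np.ndarray:
        """Label channel for a task: sex, age_class or age_regression."""
        if task == "sex":
            return self.sex
        if task == "age_class":
            return self.age_groups(scheme)
        if task == "age_regression":
            return self.age
        raise ValueError(f"unknown task {task!r}")

    def subset(self, index: Sequence[int] | np.ndarray) -> "Dataset":
        return Dataset(self.frame.iloc[np.asarray(index)].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        write_csv(self, path)


def read_csv(path: str | Path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a cohort CSV into a validated Dataset.

    ``schema`` optionally maps required canonical column names to the names
    used in the file.  Rows keep file order; rows read from disk are treated
    as real measurements unless the file carries a ``synthetic_flag`` column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in frame.columns}
        frame = frame.rename(columns=rename)
    return Dataset(frame)


def write_csv(data: Dataset, path: str | Path) -> None:
    """Write a Dataset using the canonical column order, full precision."""
    cols = ["id", "sex", "age", *FEATURES, "synthetic_flag"]
    data.frame[cols].to_csv(path, index=False, float_format="%.17g")


def group_counts(
    data: Dataset, scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME
) -> dict[str, int]:
    """Per-age-group row counts; values sum to ``len(data)``."""
    counts = {label: 0 for label in scheme.labels}
    for label in data.age_groups(scheme):
        counts[label] += 1
    return counts


def dataset_from_arrays(
    X: np.ndarray,
    sex: Iterable[str],
    age: Iterable[float],
    synthetic: Iterable[bool] | bool = False,
) -> Dataset:
    """Assemble a Dataset from a (n, 12) matrix and label vectors."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURES):
        raise ValueError(f"feature matrix must be (n, {len(FEATURES)})")
    n = X.shape[0]
    if isinstance(synthetic, (bool, np.bool_)):
        synthetic = np.full(n, bool(synthetic))
    frame = pd.DataFrame(X, columns=list(FEATURES))
    frame.insert(0, "age", np.asarray(list(age), dtype=float))
    frame.insert(0, "sex", np.asarray(list(sex)))
    frame.insert(0, "id", np.arange(n))
    frame["synthetic_flag"] = np.asarray(list(synthetic), dtype=bool)
    return Dataset(frame)
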