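"""Seeded simulator for sinus-morphometry cohorts.

The real measurements behind this kind of study are private, so the package
ships a generative stand-in: a linear Gaussian model on the nine linear
dimensions (length/width/height of the frontal and of each maxillary sinus)
with configurable sex dimorphism and age trends, a shared latent factor that
correlates right and left maxillary homologues, and volumes derived from
their own sinus' dimensions as V = c·L·W·H·exp(ε).  Deriving volume from the
dimensions builds in the redundancy that makes wrapper feature selection a
meaningful problem: a volume column carries little information its three
dimensions do not.

Every draw flows from a single integer seed; the same config yields a
byte-identical cohort.  All rows carry ``synthetic_flag=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data import FEATURES, Dataset, dataset_from_arrays

#: Indices of the nine linear dimensions in the canonical feature order.
DIMENSION_INDEX = (0, 1, 2, 4, 5, 6, 8, 9, 10)
#: Indices of the three volumes.
VOLUME_INDEX = (3, 7, 11)
#: (right, left) maxillary homologue pairs among dimension indices.
BILATERAL_PAIRS = ((4, 8), (5, 9), (6, 10))
#: (volume index, (L, W, H) indices) for the coupling rule.
VOLUME_PARENTS = ((3, (0, 1, 2)), (7, (4, 5, 6)), (11, (8, 9, 10)))

# Baseline adult magnitudes (mm / mm³).  Chosen once so that CSVs read like
# plausible sinus morphometry; they claim nothing about any real cohort's
# distribution.  Volume baselines are used only when volume coupling is off.
_DEFAULT_MEANS = {
    "FSL": 13.0, "FSW": 48.0, "FSH": 25.0, "FSV": 6500.0,
    "RMSL": 38.0, "RMSW": 28.0, "RMSH": 33.0, "RMSV": 15000.0,
    "LMSL": 38.0, "LMSW": 28.0, "LMSH": 33.0, "LMSV": 15000.0,
}
_DEFAULT_SDS = {
    "FSL": 3.0, "FSW": 8.0, "FSH": 5.0, "FSV": 2000.0,
    "RMSL": 4.0, "RMSW": 4.0, "RMSH": 4.0, "RMSV": 4000.0,
    "LMSL": 4.0, "LMSW": 4.0, "LMSH": 4.0, "LMSV": 4000.0,
}

# Default standardized male−female shift per feature: moderate dimorphism on
# every linear dimension, in line with the direction reported across the
# craniofacial-morphometry literature (male sinuses larger on average).
_DEFAULT_SEX_EFFECT = {name: (0.8 if name in
                              {FEATURES[i] for i in DIMENSION_INDEX} else 0.0)
                       for name in FEATURES}
# Default standardized slope per decade of age, centred at 35 years.
_DEFAULT_AGE_EFFECT = {name: (0.15 if name in
                              {FEATURES[i] for i in DIMENSION_INDEX} else 0.0)
                       for name in FEATURES}


def _as_vector(value, default: dict[str, float]) -> np.ndarray:
    if value is None:
        return np.array([default[name] for name in FEATURES], dtype=float)
    arr = np.asarray(value, dtype=float)
    if arr.shape == ():
        arr = np.full(len(FEATURES), float(arr))
    if arr.shape != (len(FEATURES),):
        raise ValueError(f"expected a length-{len(FEATURES)} vector")
    return arr


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the target cohort shape: 240 subjects, 129 female / 111
    male, ages uniform on [18, 52].  ``sex_effect`` and ``age_effect`` are
    standardized shifts (per feature, male−female; per decade of age);
    ``bilateral_rho`` is the latent correlation between right and left
    maxillary homologues; ``volume_c``/``volume_sigma`` parameterize the
    multiplicative volume–dimension coupling.  With ``volume_coupling``
    off, volumes are drawn independently like any other feature — used by
    the planted-relevance benchmark where noise features must be pure noise.
    """

    n: int = 240
    female_fraction: float = 129 / 240
    age_range: tuple[float, float] = (18.0, 52.0)
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    sex_effect: np.ndarray | float | None = None
    age_effect: np.ndarray | float | None = None
    bilateral_rho: float = 0.7
    volume_coupling: bool = True
    volume_c: float = 0.43
    volume_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("cohort size must be at least 4")
        if not 0.0 < self.female_fraction < 1.0:
            raise ValueError("female_fraction must lie in (0, 1)")
        if not 0.0 <= self.bilateral_rho < 1.0:
            raise ValueError("bilateral_rho must lie in [0, 1)")
        self.means = _as_vector(self.means, _DEFAULT_MEANS)
        self.sds = _as_vector(self.sds, _DEFAULT_SDS)
        if np.any(self.sds <= 0):
            raise ValueError("all feature SDs must be positive")
        self.sex_effect = _as_vector(self.sex_effect, _DEFAULT_SEX_EFFECT)
        self.age_effect = _as_vector(self.age_effect, _DEFAULT_AGE_EFFECT)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("means", "sds", "sex_effect", "age_effect"):
            d[key] = list(map(float, d[key]))
        d["age_range"] = list(d["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def _draw_positive(rng: np.random.Generator, draw, shape) -> np.ndarray:
    """Rejection-sample elementwise until strictly positive."""
    x = draw(shape)
    for _ in range(1000):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = draw(int(bad.sum()))
    raise RuntimeError("could not produce strictly positive measurements")


def generate(cfg: SimConfig) -> Dataset:
    """Draw one cohort under ``cfg``; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    n_female = int(round(n * cfg.female_fraction))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    male = (sex == "M").astype(float)

    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, size=n)
    age_std = (age - 35.0) / 10.0

    rho = cfg.bilateral_rho
    X = np.empty((n, len(FEATURES)))
    # latent factors shared by the bilateral pairs, one per homologue triple
    latents = {pair: rng.standard_normal(n) for pair in BILATERAL_PAIRS}
    paired = {i: pair for pair in BILATERAL_PAIRS for i in pair}

    def noise(j: int) -> np.ndarray:
        if j in paired:
            z = latents[paired[j]]
            return np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        return rng.standard_normal(n)

    independent = list(DIMENSION_INDEX) if cfg.volume_coupling else list(range(len(FEATURES)))
    for j in independent:
        mean_shift = cfg.sex_effect[j] * male + cfg.age_effect[j] * age_std
        e = noise(j)
        x = cfg.means[j] + cfg.sds[j] * (mean_shift + e)
        bad = x <= 0
        while bad.any():  # truncate to the positive orthant by resampling
            k = int(bad.sum())
            x[bad] = cfg.means[j] + cfg.sds[j] * (mean_shift[bad] + rng.standard_normal(k))
            bad = x <= 0
        X[:, j] = x

    if cfg.volume_coupling:
        for v, (l, w, h) in VOLUME_PARENTS:
            eps = rng.normal(0.0, cfg.volume_sigma, size=n)
            X[:, v] = cfg.volume_c * X[:, l] * X[:, w] * X[:, h] * np.exp(eps)

    return dataset_from_arrays(X, sex, age, synthetic=True)


def planted_relevance_cohort(
    n: int,
    informative_set: Sequence[int],
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[Dataset, np.ndarray]:
    """Cohort with a known-relevant feature subset, for selector benchmarks.

    Sex carries a standardized mean shift of ``effect`` on each feature in
    ``informative_set`` and exactly zero elsewhere; all twelve features are
    drawn independently (volume coupling and bilateral correlation off), so
    the complement of the informative set is pure noise.  Returns the cohort
    and the ground-truth boolean mask over the canonical feature order.
    """
    informative = sorted(set(int(i) for i in informative_set))
    if not informative:
        raise ValueError("informative_set must be non-empty")
    if len(informative) >= len(FEATURES):
        raise ValueError("informative_set must be a proper subset of the features")
    if informative[0] < 0 or informative[-1] >= len(FEATURES):
        raise ValueError("feature index out of range")
    sex_effect = np.zeros(len(FEATURES))
    sex_effect[informative] = effect
    cfg = SimConfig(
        n=n,
        female_fraction=0.5,
        sex_effect=sex_effect,
        age_effect=0.0,
        bilateral_rho=0.0,
        volume_coupling=False,
        seed=seed,
    )
    mask = np.zeros(len(FEATURES), dtype=bool)
    mask[informative] = True
    return generate(cfg), mask
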