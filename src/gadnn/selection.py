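"""Genetic-algorithm wrapper feature selection around the deep network.

A candidate solution is a binary chromosome of length 12 (one bit per
measurement in the canonical feature order).  Fitness is the held-out
performance of the deep network trained on the masked features: validation
accuracy for classification, 1/(1+RMSE) for regression.  The validation fold
is carved once from the training partition — never from the test partition —
so the test metrics reported after selection stay honest.  Each mask is
trained with one fixed seed and a reduced epoch budget, which makes fitness a
deterministic, cacheable function of the mask; the winning mask is then
retrained at the full epoch budget.

The GA itself is a small, standard one: tournament selection (size 2),
single-point crossover, independent bit-flip mutation at rate 1/L, and one
elite carried over unchanged, so the best-so-far fitness never decreases.
All-zero chromosomes are repaired by setting one random bit rather than
wasting an evaluation on an empty feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, MetaEstimatorMixin, clone, is_classifier
from sklearn.model_selection import train_test_split

from .data import FEATURES, Dataset
from .metrics import EvalReport, RegressionReport, classification_report, regression_report
from .network import DNNClassifier, DNNRegressor, TrainConfig
from .preprocess import SplitDataset, minmax_normalize, smote_balance, SmoteConfig, split as split_dataset

__all__ = [
    "GAConfig", "GadnnResult", "GeneticFeatureSelector",
    "init_population", "crossover", "mutate", "evolve",
    "make_dnn_fitness", "gadnn_select",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the selector's genetic algorithm.

    All values are this package's defaults for a desk-scale run; none is a
    published setting.  ``mutation_rate`` of None means 1/L per bit.
    ``fitness_epochs`` is the reduced training budget used while screening
    masks; the final model is retrained at the full epoch count.
    """

    population_size: int = 20
    generations: int = 15
    tournament_size: int = 2
    crossover_prob: float = 0.8
    mutation_rate: float | None = None
    elitism: int = 1
    fitness_epochs: int = 30
    fitness_batch_size: int = 64
    fitness_learning_rate: float = 0.02
    fitness_dropout: float = 0.2
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population must have at least 2 chromosomes")
        if self.generations < 1:
            raise ValueError("at least one generation required")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover probability must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero chromosomes get one uniformly chosen bit set."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, mask.size)] = True
    return mask


def init_population(cfg: GAConfig, n_features: int) -> np.ndarray:
    """Seeded initial population: each bit an independent fair coin."""
    if n_features < 1:
        raise ValueError("need at least one candidate feature")
    rng = np.random.default_rng(cfg.seed)
    pop = rng.random((cfg.population_size, n_features)) < 0.5
    for i in range(pop.shape[0]):
        pop[i] = _repair(pop[i], rng)
    return pop


def crossover(
    parent1: np.ndarray, parent2: np.ndarray, point: int, apply: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point suffix exchange at ``point`` (1 ≤ point ≤ L−1)."""
    parent1 = np.asarray(parent1, dtype=bool)
    parent2 = np.asarray(parent2, dtype=bool)
    if parent1.shape != parent2.shape:
        raise ValueError("parents must have equal length")
    if not apply:
        return parent1.copy(), parent2.copy()
    L = parent1.size
    if not 1 <= point <= L - 1:
        raise ValueError(f"crossover point must lie in [1, {L - 1}]")
    c1 = np.concatenate([parent1[:point], parent2[point:]])
    c2 = np.concatenate([parent2[:point], parent1[point:]])
    return c1, c2


def mutate(mask: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-bit flips at ``rate``, followed by all-zero repair."""
    mask = np.asarray(mask, dtype=bool)
    flips = rng.random(mask.size) < rate
    return _repair(mask ^ flips, rng)


def evolve(
    cfg: GAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    n_features: int,
) -> tuple[np.ndarray, list[float]]:
    """Run the GA; returns the best-ever mask and best-so-far per generation.

    The history has one entry for the initial population and one per
    generation; elitism makes it non-decreasing.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_features
    pop = init_population(cfg, n_features)
    fitness = np.array([fitness_fn(m) for m in pop])

    def rank_key(i: int) -> tuple[float, int]:
        # exact fitness ties break toward the smaller feature set (parsimony)
        return (fitness[i], -int(pop[i].sum()))

    best_idx = max(range(len(pop)), key=rank_key)
    best_mask, best_fit = pop[best_idx].copy(), float(fitness[best_idx])
    history = [best_fit]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
        return pop[max(idx, key=rank_key)]

    for _ in range(cfg.generations):
        order = sorted(range(cfg.population_size), key=rank_key, reverse=True)
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_prob:
                point = int(rng.integers(1, n_features))
                c1, c2 = crossover(p1, p2, point)
            else:
                c1, c2 = p1.copy(), p2.copy()
            new_pop.append(mutate(c1, rate, rng))
            if len(new_pop) < cfg.population_size:
                new_pop.append(mutate(c2, rate, rng))
        pop = np.array(new_pop)
        fitness = np.array([fitness_fn(m) for m in pop])
        gen_best = max(range(len(pop)), key=rank_key)
        better = fitness[gen_best] > best_fit or (
            fitness[gen_best] == best_fit and pop[gen_best].sum() < best_mask.sum()
        )
        if better:
            best_fit = float(fitness[gen_best])
            best_mask = pop[gen_best].copy()
        history.append(best_fit)
    return best_mask, history


# ------------------------------------------------------------------- fitness

def make_dnn_fitness(
    X_train: np.ndarray,
    y_train: np.ndarray,
    task: str,
    cfg: GAConfig,
) -> Callable[[np.ndarray], float]:
    """Cached mask → held-out score function backed by the deep network.

    A validation fold of ``cfg.val_fraction`` is carved once from the given
    training arrays (stratified for classification) and shared by every
    mask, so mask comparisons are paired; training uses one fixed seed and
    ``cfg.fitness_epochs`` epochs.  Screening deliberately uses a
    resource-constrained learner (reduced epochs, lower learning rate,
    heavier dropout than the final model): a learner strong enough to
    saturate validation accuracy scores every adequate mask identically and
    gives the search nothing to discriminate on, whereas a constrained one
    is measurably hurt by irrelevant inputs.  The returned callable exposes
    its cache as ``.cache``.
    """
    dropout = cfg.fitness_dropout
    learning_rate = cfg.fitness_learning_rate
    classification = task in ("sex", "age_class")
    idx_fit, idx_val = train_test_split(
        np.arange(len(y_train)),
        test_size=cfg.val_fraction,
        random_state=cfg.seed,
        stratify=y_train if classification else None,
    )
    Xf, Xv = X_train[idx_fit], X_train[idx_val]
    yf, yv = y_train[idx_fit], y_train[idx_val]
    fit_seed = cfg.seed + 1
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("cannot evaluate an all-zero feature mask")
        key = mask.tobytes()
        if key in cache:
            return cache[key]
        if classification:
            est = DNNClassifier(epochs=cfg.fitness_epochs,
                                batch_size=cfg.fitness_batch_size,
                                dropout=dropout, learning_rate=learning_rate,
                                random_state=fit_seed)
            est.fit(Xf[:, mask], yf)
            score = float(np.mean(est.predict(Xv[:, mask]) == yv))
        else:
            est = DNNRegressor(epochs=cfg.fitness_epochs,
                               batch_size=cfg.fitness_batch_size,
                               dropout=dropout, learning_rate=learning_rate,
                               random_state=fit_seed)
            est.fit(Xf[:, mask], yf)
            rmse = regression_report(yv, est.predict(Xv[:, mask])).rmse
            score = 1.0 / (1.0 + rmse)
        cache[key] = score
        return score

    fitness.cache = cache
    fitness.n_val = len(idx_val) if classification else None
    return fitness


# ------------------------------------------------------- sklearn-style facade

class GeneticFeatureSelector(BaseEstimator, MetaEstimatorMixin):
    """GA wrapper feature selection around any sklearn-style estimator.

    ``estimator`` is cloned and refit for every distinct mask on an internal
    train/validation carve-out of the data passed to :meth:`fit`; fitness is
    validation accuracy for classifiers and 1/(1+RMSE) for regressors.

    Attributes after fit: ``support_`` (boolean mask over columns),
    ``best_fitness_``, ``history_`` (best-so-far per generation),
    ``n_evaluations_`` (distinct masks trained).
    """

    def __init__(self, estimator=None, population_size=20, generations=15,
                 tournament_size=2, crossover_prob=0.8, mutation_rate=None,
                 elitism=1, val_fraction=0.2, random_state=0):
        self.estimator = estimator
        self.population_size = population_size
        self.generations = generations
        self.tournament_size = tournament_size
        self.crossover_prob = crossover_prob
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            tournament_size=self.tournament_size,
            crossover_prob=self.crossover_prob,
            mutation_rate=self.mutation_rate,
            elitism=self.elitism,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        est = self.estimator if self.estimator is not None else DNNClassifier(
            epochs=30, batch_size=64, learning_rate=0.01, dropout=0.2,
            random_state=self.random_state)
        cfg = self._ga_config()
        classifier = is_classifier(est)
        idx_fit, idx_val = train_test_split(
            np.arange(len(y)), test_size=self.val_fraction,
            random_state=self.random_state,
            stratify=y if classifier else None,
        )
        cache: dict[bytes, float] = {}

        def fitness(mask: np.ndarray) -> float:
            key = mask.tobytes()
            if key in cache:
                return cache[key]
            model = clone(est)
            model.fit(X[np.ix_(idx_fit, np.flatnonzero(mask))],
                      y[idx_fit])
            pred = model.predict(X[np.ix_(idx_val, np.flatnonzero(mask))])
            if classifier:
                score = float(np.mean(pred == y[idx_val]))
            else:
                score = 1.0 / (1.0 + regression_report(
                    y[idx_val].astype(float), pred).rmse)
            cache[key] = score
            return score

        _, history = evolve(cfg, fitness, X.shape[1])
        self.support_ = parsimonious_best(
            cache, X.shape[1], len(idx_val) if classifier else None)
        self.history_ = history
        self.best_fitness_ = fitness(self.support_)
        self.n_evaluations_ = len(cache)
        self.n_features_in_ = X.shape[1]
        self.fitness_fn_ = fitness  # the exact objective the GA maximized
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def parsimonious_best(
    cache: dict[bytes, float], n_features: int, n_val: int | None
) -> np.ndarray:
    """Most parsimonious evaluated mask within one standard error of the best.

    The one-standard-error rule from the model-selection literature: wrapper
    fitness on a finite validation fold is noisy, so among masks whose score
    is statistically indistinguishable from the maximum (within
    sqrt(p(1-p)/n_val) for an accuracy p), the smallest feature set is the
    better-supported hypothesis.  With ``n_val`` None (regression fitness,
    where no binomial SE applies) only exact ties with the best are eligible.
    """
    items = [(np.frombuffer(key, dtype=bool), fit) for key, fit in cache.items()]
    best_fit = max(fit for _, fit in items)
    if n_val:
        se = float(np.sqrt(max(best_fit * (1.0 - best_fit), 0.0) / n_val))
    else:
        se = 0.0
    eligible = [(m, f) for m, f in items if f >= best_fit - se]
    mask, _ = min(eligible, key=lambda mf: (int(mf[0].sum()), -mf[1]))
    return mask.copy()


# ------------------------------------------------------------- full pipeline

@dataclass
class GadnnResult:
    """Outcome of a GA-selected deep-network run."""

    mask: np.ndarray
    selected: tuple[str, ...]
    dropped: tuple[str, ...]
    report: EvalReport | RegressionReport
    history: list[float]
    n_evaluations: int


def _prepare(data: Dataset, task: str, test_fraction: float, seed: int,
             smote_order: str, use_smote: bool, smote_k: int = 5):
    """Shared preprocessing: (SMOTE) → split → min–max scale → label arrays."""
    if task == "age_regression":
        use_smote = False  # oversampling a continuous target is meaningless
    labels = data.labels(task) if task != "age_regression" else None
    if use_smote and smote_order == "paper":
        data, labels = smote_balance(data, labels, SmoteConfig(k=smote_k, seed=seed))
    parts = split_dataset(data, labels, test_fraction=test_fraction,
                          seed=seed, smote_order=smote_order)
    if use_smote and smote_order == "safe":
        train_labels = parts.train.labels(task)
        balanced, _ = smote_balance(parts.train, train_labels,
                                    SmoteConfig(k=smote_k, seed=seed))
        parts = SplitDataset(train=balanced, test=parts.test,
                             test_fraction=test_fraction, seed=seed,
                             smote_order="safe")
    Xtr, Xte, scaler = minmax_normalize(parts.train.features, parts.test.features)
    ytr = parts.train.labels(task)
    yte = parts.test.labels(task)
    return parts, Xtr, ytr, Xte, yte, scaler


def gadnn_select(
    data: Dataset,
    task: str,
    ga_cfg: GAConfig = GAConfig(),
    net_cfg: TrainConfig = TrainConfig(),
    test_fraction: float = 0.2,
    smote_order: str = "paper",
    use_smote: bool = True,
    dropout: float = 0.1,
) -> GadnnResult:
    """Run the full select-then-retrain procedure on a cohort.

    Preprocesses the cohort (balance, split, scale), searches feature masks
    with the GA, retrains the deep network on the winning mask at the full
    epoch budget, and scores it on the untouched test partition.
    """
    _, Xtr, ytr, Xte, yte, _ = _prepare(
        data, task, test_fraction, ga_cfg.seed, smote_order, use_smote)
    fitness = make_dnn_fitness(Xtr, ytr, task, ga_cfg)
    _, history = evolve(ga_cfg, fitness, Xtr.shape[1])
    # one-SE parsimony: smallest evaluated mask statistically tied with best
    mask = parsimonious_best(fitness.cache, Xtr.shape[1], fitness.n_val)

    if task == "age_regression":
        final = DNNRegressor(epochs=net_cfg.epochs, batch_size=net_cfg.batch_size,
                             learning_rate=net_cfg.learning_rate,
                             dropout=dropout, random_state=net_cfg.seed)
        final.fit(Xtr[:, mask], ytr.astype(float))
        report = regression_report(yte.astype(float), final.predict(Xte[:, mask]))
    else:
        final = DNNClassifier(epochs=net_cfg.epochs, batch_size=net_cfg.batch_size,
                              learning_rate=net_cfg.learning_rate, loss=net_cfg.loss,
                              dropout=dropout, random_state=net_cfg.seed)
        final.fit(Xtr[:, mask], ytr)
        report = classification_report(yte, final.predict(Xte[:, mask]),
                                       classes=sorted(set(ytr) | set(yte)))
    names = np.array(FEATURES)
    return GadnnResult(
        mask=mask,
        selected=tuple(names[mask]),
        dropped=tuple(names[~mask]),
        report=report,
        history=history,
        n_evaluations=len(fitness.cache),
    )
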