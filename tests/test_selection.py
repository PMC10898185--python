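import itertools

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression

from gadnn import GAConfig, GeneticFeatureSelector, evolve, planted_relevance_cohort
from gadnn.selection import crossover, init_population, make_dnn_fitness, mutate


def test_initial_population_is_seeded_and_repaired():
    cfg = GAConfig(population_size=50, seed=1)
    pop = init_population(cfg, 12)
    assert pop.shape == (50, 12)
    assert pop.any(axis=1).all()  # no all-zero chromosome survives
    np.testing.assert_array_equal(pop, init_population(cfg, 12))
    assert not np.array_equal(pop, init_population(GAConfig(population_size=50, seed=2), 12))


def test_single_point_crossover_swaps_suffixes():
    p1 = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
    p2 = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
    c1, c2 = crossover(p1, p2, point=3)
    np.testing.assert_array_equal(c1, np.ones(6, dtype=bool))
    np.testing.assert_array_equal(c2, np.zeros(6, dtype=bool))
    # the all-zero child is repaired on its way through mutation
    repaired = mutate(c2, rate=0.0, rng=np.random.default_rng(0))
    assert repaired.sum() == 1
    with pytest.raises(ValueError):
        crossover(p1, p2, point=6)
    same1, same2 = crossover(p1, p2, point=3, apply=False)
    np.testing.assert_array_equal(same1, p1)


def test_mutation_rate_extremes():
    rng = np.random.default_rng(0)
    mask = np.array([1, 0, 1, 1], dtype=bool)
    np.testing.assert_array_equal(mutate(mask, 0.0, rng), mask)
    flipped = mutate(mask, 1.0, np.random.default_rng(1))
    np.testing.assert_array_equal(flipped, ~mask)


def test_evolve_finds_allones_under_popcount_fitness():
    hits = 0
    for seed in range(10):
        best, history = evolve(GAConfig(seed=seed), lambda m: m.sum() / 12.0, 12)
        hits += bool(best.all())
        assert history == sorted(history)  # elitism: non-decreasing
    assert hits >= 9


def test_evolve_matches_exhaustive_search_at_l4():
    rng = np.random.default_rng(42)
    for trial in range(10):
        table = {m: rng.random() for m in itertools.product([0, 1], repeat=4)
                 if any(m)}
        fitness = lambda m: table[tuple(int(b) for b in m)]
        best, _ = evolve(GAConfig(generations=15, seed=trial), fitness, 4)
        brute = max(table.values())
        assert fitness(best) == pytest.approx(brute)


def test_constant_fitness_returns_valid_mask_with_flat_history():
    best, history = evolve(GAConfig(generations=5, seed=0), lambda m: 0.4, 8)
    assert best.any()
    assert history == [0.4] * 6


def test_degenerate_ga_keeps_best_constant():
    cfg = GAConfig(population_size=8, generations=6, crossover_prob=0.0,
                   mutation_rate=0.0, elitism=1, seed=3)
    calls = []
    def fitness(m):
        calls.append(m.copy())
        return float(m.sum())
    best, history = evolve(cfg, fitness, 10)
    assert len(set(history)) == 1  # no variation operators -> no improvement


def test_evaluation_budget_respected():
    cfg = GAConfig(population_size=10, generations=5, seed=0)
    seen = set()
    def fitness(m):
        seen.add(m.tobytes())
        return float(m.sum())
    evolve(cfg, fitness, 12)
    assert len(seen) <= 10 * 6  # initial population + one per generation


def test_dnn_fitness_is_cached_and_deterministic():
    data, mask = planted_relevance_cohort(120, [0, 1, 2], effect=2.0, seed=0)
    X, y = data.features, data.sex
    cfg = GAConfig(fitness_epochs=3, seed=0)
    fitness = make_dnn_fitness(X, y, "sex", cfg)
    m = np.zeros(12, dtype=bool)
    m[:3] = True
    v1 = fitness(m)
    v2 = fitness(m)
    assert v1 == v2
    assert len(fitness.cache) == 1
    with pytest.raises(ValueError):
        fitness(np.zeros(12, dtype=bool))


def test_selector_maximizes_its_objective_with_linear_estimator():
    """The GA's mask scores at least as well, on the GA's own held-out
    objective, as both the full feature set and the planted ground truth."""
    from gadnn.preprocess import minmax_normalize

    data, truth = planted_relevance_cohort(400, [0, 2, 4, 6, 8, 10],
                                           effect=2.0, seed=7)
    X, _, _ = minmax_normalize(data.features)
    sel = GeneticFeatureSelector(
        estimator=LogisticRegression(max_iter=500),
        population_size=20, generations=12, random_state=7,
    ).fit(X, data.sex)
    full = np.ones(12, dtype=bool)
    best_raw = sel.history_[-1]
    assert best_raw >= sel.fitness_fn_(full)
    assert best_raw >= sel.fitness_fn_(truth)
    assert sel.best_fitness_ == sel.fitness_fn_(sel.support_)
    # the returned mask obeys the one-SE parsimony rule
    n_val = round(0.2 * len(data))
    se = np.sqrt(best_raw * (1 - best_raw) / n_val)
    assert sel.best_fitness_ >= best_raw - se - 1e-12
    # on a strongly separable cohort the winning mask is genuinely good
    assert sel.best_fitness_ >= 0.9
    assert sel.history_ == sorted(sel.history_)
    assert sel.transform(X).shape[1] == sel.support_.sum()


def test_selector_is_sklearn_compatible():
    sel = GeneticFeatureSelector(population_size=4, generations=2, random_state=1)
    params = sel.get_params()
    assert params["population_size"] == 4
    assert clone(sel).get_params() == params


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(population_size=1)
    with pytest.raises(ValueError):
        GAConfig(crossover_prob=1.5)
    with pytest.raises(ValueError):
        GAConfig(elitism=25)
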