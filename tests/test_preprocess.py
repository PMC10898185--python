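import numpy as np
import pytest

from gadnn import (
    SmoteConfig,
    dataset_from_arrays,
    decode,
    group_counts,
    minmax_normalize,
    one_hot,
    smote_balance,
    split,
)
from gadnn.data import FEATURES


def _segment_oracle(synthetic_rows, real_rows, k, atol=1e-8):
    """Brute-force check: each synthetic point lies on the segment between
    some real point and one of its k nearest neighbours (all-pairs scan)."""
    diffs = real_rows[:, None, :] - real_rows[None, :, :]
    dist = np.sqrt((diffs**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    neighbours = np.argsort(dist, axis=1)[:, :k]
    for s in synthetic_rows:
        found = False
        for i, x in enumerate(real_rows):
            for j in neighbours[i]:
                seg = real_rows[j] - x
                denom = seg @ seg
                if denom == 0:
                    continue
                u = (s - x) @ seg / denom
                if -atol <= u <= 1 + atol and np.allclose(x + u * seg, s, atol=atol):
                    found = True
                    break
            if found:
                break
        if not found:
            return False
    return True


def test_smote_balances_to_majority(table2_cohort):
    labels = table2_cohort.age_groups()
    balanced, new_labels = smote_balance(table2_cohort, labels, SmoteConfig(seed=0))
    counts = group_counts(balanced)
    assert counts == {"A": 90, "B": 90, "C": 90, "D": 90}
    assert len(new_labels) == 360
    # original rows lead, byte-identical
    np.testing.assert_array_equal(
        balanced.features[: len(table2_cohort)], table2_cohort.features)
    assert not balanced.synthetic_flag[: len(table2_cohort)].any()
    assert balanced.synthetic_flag[len(table2_cohort):].all()


def test_smote_leaves_balanced_classes_untouched():
    rng = np.random.default_rng(1)
    data = dataset_from_arrays(
        rng.lognormal(3, 0.2, size=(20, 12)),
        ["F"] * 10 + ["M"] * 10,
        rng.uniform(18, 50, 20),
    )
    balanced, labels = smote_balance(data, data.sex)
    assert len(balanced) == 20
    assert not balanced.synthetic_flag.any()


def test_smote_points_are_convex_combinations_of_neighbours():
    rng = np.random.default_rng(2)
    n_min, n_maj, k = 12, 40, 5
    X = np.vstack([
        rng.lognormal(3, 0.3, size=(n_min, 12)),
        rng.lognormal(3.4, 0.3, size=(n_maj, 12)),
    ])
    sex = np.array(["F"] * n_min + ["M"] * n_maj)
    data = dataset_from_arrays(X, sex, rng.uniform(18, 50, n_min + n_maj))
    balanced, _ = smote_balance(data, sex, SmoteConfig(k=k, seed=3))
    synth = balanced.features[balanced.synthetic_flag]
    assert len(synth) == n_maj - n_min
    assert _segment_oracle(synth, X[:n_min], k)


def test_smote_reduces_k_with_warning_and_rejects_singletons():
    rng = np.random.default_rng(4)
    X = rng.lognormal(3, 0.2, size=(13, 12))
    data = dataset_from_arrays(X, ["F"] * 3 + ["M"] * 10, rng.uniform(18, 50, 13))
    with pytest.warns(UserWarning, match="reducing SMOTE k to 2"):
        balanced, _ = smote_balance(data, data.sex, SmoteConfig(k=5, seed=0))
    assert (balanced.sex == "F").sum() == 10

    single = dataset_from_arrays(X[:11], ["F"] + ["M"] * 10,
                                 rng.uniform(18, 50, 11))
    with pytest.raises(ValueError, match="single member"):
        smote_balance(single, single.sex)


def test_smote_synthetic_ages_stay_inside_their_bin(table2_cohort):
    labels = table2_cohort.age_groups()
    balanced, new_labels = smote_balance(table2_cohort, labels, SmoteConfig(seed=1))
    assert (balanced.age_groups() == new_labels).all()


def test_minmax_formula_and_degenerate_column():
    train = np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]])
    scaled, _, scaler = minmax_normalize(train)
    np.testing.assert_allclose(scaled[:, 0], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(scaled[:, 1], [0.0, 0.0, 0.0])
    # test values outside the training range are not clipped
    test = np.array([[8.0, 5.0]])
    assert scaler.transform(test)[0, 0] == pytest.approx(1.5)


def test_minmax_inverse_recovers_train():
    rng = np.random.default_rng(0)
    train = rng.lognormal(3, 0.5, size=(50, 12))
    scaled, _, scaler = minmax_normalize(train)
    recovered = scaler.inverse_transform(scaled)
    np.testing.assert_allclose(recovered, train, rtol=1e-9)


def test_one_hot_and_decode_rules():
    classes = ["A", "B", "C", "D"]
    mat = one_hot(["B"], classes)
    np.testing.assert_array_equal(mat, [[0, 1, 0, 0]])
    assert (one_hot(["A", "C", "D"], classes).sum(axis=1) == 1).all()
    assert decode([0.1, 0.7, 0.1, 0.1], classes)[0] == "B"
    # ties break toward the lowest class index
    assert decode([0.5, 0.5, 0.0, 0.0], classes)[0] == "A"
    with pytest.raises(ValueError, match="E"):
        one_hot(["E"], classes)


def test_split_is_stratified_and_seeded(table2_cohort):
    balanced, labels = smote_balance(table2_cohort, table2_cohort.age_groups(),
                                     SmoteConfig(seed=0))
    parts = split(balanced, labels, test_fraction=0.2, seed=7)
    assert len(parts.train) == 288 and len(parts.test) == 72
    test_counts = group_counts(parts.test)
    assert all(v == 18 for v in test_counts.values())
    # disjoint by row identity
    assert not set(parts.train.frame["id"]) & set(parts.test.frame["id"])
    # reproducible
    again = split(balanced, labels, test_fraction=0.2, seed=7)
    np.testing.assert_array_equal(parts.test.features, again.test.features)


def test_split_rejects_degenerate_inputs(small_cohort):
    with pytest.raises(ValueError):
        split(small_cohort, small_cohort.sex, test_fraction=0.0)
    labels = np.array(["X"] + ["Y"] * (len(small_cohort) - 1))
    with pytest.raises(ValueError, match="stratum"):
        split(small_cohort, labels)
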