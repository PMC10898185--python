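import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest

from gadnn import (
    DNNClassifier,
    DNNRegressor,
    NetworkSpec,
    TrainConfig,
    build_network,
    linear,
    relu,
    softmax,
)
from gadnn.network import DEFAULT_TRUNK, _Network
from gadnn.preprocess import minmax_normalize


# ---------------------------------------------------------------- activations

def test_relu_and_linear_formulas():
    assert relu(-2.0) == 0.0
    assert relu(3.0) == 3.0
    np.testing.assert_array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])
    assert linear(3.7) == 3.7


def test_softmax_symmetry_and_overflow_safety():
    np.testing.assert_allclose(softmax([0.0, 0.0]), [0.5, 0.5])
    # exact value: 1/(1+e^-1000) is 1.0 to double precision
    np.testing.assert_allclose(softmax([1000.0, 0.0]), [1.0, 0.0], atol=1e-12)
    big = softmax(np.full(4, 1e6))
    np.testing.assert_allclose(big, 0.25)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=8))
def test_softmax_sums_to_one_and_is_shift_invariant(xs):
    v = np.array(xs)
    p = softmax(v)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    assert (p > 0).all()
    np.testing.assert_allclose(softmax(v + 17.3), p, atol=1e-9)


# -------------------------------------------------------------- architecture

@pytest.mark.parametrize("task,head", [("sex", 2), ("age_class", 4),
                                       ("age_regression", 1)])
def test_head_width_by_task(task, head):
    spec = build_network(12, task)
    assert spec.head_dim == head


def test_trunk_is_fixed_funnel_with_nine_main_layers():
    spec = build_network(12, "age_class")
    assert spec.trunk == (1024, 512, 256, 128, 64, 32, 16, 8)
    assert spec.n_main_layers == 9
    assert spec.trunk_activations == ("relu",) * 7 + ("softmax",)
    assert spec.head_activation == "linear"
    net = _Network(spec, seed=0)
    assert net.layers[0].W.shape == (12, 1024)
    assert net.head_W.shape == (8, 4)
    # dropping features only narrows the input, never the trunk
    assert build_network(9, "age_class").trunk == spec.trunk


def test_invalid_shapes_rejected():
    with pytest.raises(ValueError):
        build_network(0, "sex")
    with pytest.raises(ValueError):
        build_network(12, "weight")
    with pytest.raises(ValueError):
        NetworkSpec(input_dim=12, trunk=(64, 128), trunk_activations=("relu", "relu"))


def test_train_config_defaults_and_validation():
    assert TrainConfig().epochs == 100
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)


# ------------------------------------------------------------------ training

def _blobs(n=200, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 12))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X[n // 2:] += sep
    Xs, _, _ = minmax_normalize(X)
    return Xs, y


def test_separated_blobs_are_learned_perfectly():
    X, y = _blobs()
    clf = DNNClassifier(epochs=50, random_state=0).fit(X, y)
    assert np.mean(clf.predict(X) == y) == 1.0
    assert len(clf.loss_curve_) == 50
    assert np.isfinite(clf.loss_curve_).all()


def test_training_is_bit_reproducible():
    X, y = _blobs(n=80)
    a = DNNClassifier(epochs=10, random_state=3).fit(X, y)
    b = DNNClassifier(epochs=10, random_state=3).fit(X, y)
    assert a.loss_curve_ == b.loss_curve_
    np.testing.assert_array_equal(a.decision_function(X), b.decision_function(X))
    c = DNNClassifier(epochs=10, random_state=4).fit(X, y)
    assert a.loss_curve_ != c.loss_curve_


def test_prediction_is_deterministic_and_shaped():
    X, y = _blobs(n=80)
    clf = DNNClassifier(epochs=5, random_state=0).fit(X, y)
    s1 = clf.decision_function(X)
    s2 = clf.decision_function(X)
    np.testing.assert_array_equal(s1, s2)
    assert s1.shape == (80, 2)
    with pytest.raises(ValueError, match="features"):
        clf.predict(X[:, :5])


def test_untrained_network_predicts_at_chance():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(500, 12))
    y = np.array(["A", "B"] * 250)
    clf = DNNClassifier(epochs=0, random_state=1).fit(X, y)
    hits = int(np.sum(clf.predict(X) == y))
    assert binomtest(hits, 500, 0.5).pvalue > 1e-3
    assert clf.loss_curve_ == []


def test_memorizes_random_labels_at_small_n():
    rng = np.random.default_rng(1)
    X, _, _ = minmax_normalize(rng.normal(size=(50, 12)))
    y = rng.choice(["A", "B"], size=50)
    clf = DNNClassifier(epochs=500, random_state=0).fit(X, y)
    assert np.mean(clf.predict(X) == y) >= 0.99


def test_divergence_raises_instead_of_silent_nan():
    X, y = _blobs(n=80)
    with pytest.raises(FloatingPointError, match="diverged"):
        DNNClassifier(epochs=50, learning_rate=1e4, random_state=0).fit(X, y)


def test_dimension_mismatch_and_target_checks():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 6))
    with pytest.raises(ValueError):
        DNNClassifier(epochs=1).fit(X, np.array(["A"] * 40))  # single class
    reg = DNNRegressor(epochs=1, random_state=0).fit(X, rng.normal(size=40))
    with pytest.raises(ValueError, match="features"):
        reg.predict(X[:, :3])


def test_regressor_tracks_scale_of_targets():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(300, 12))
    y = 35.0 + 8.0 * X[:, 0]
    Xs, _, _ = minmax_normalize(X)
    reg = DNNRegressor(epochs=60, random_state=0).fit(Xs, y)
    pred = reg.predict(Xs)
    assert abs(pred.mean() - y.mean()) < 2.0
    assert np.corrcoef(pred, y)[0, 1] > 0.9


def test_sklearn_clone_compatibility():
    from sklearn.base import clone
    clf = DNNClassifier(epochs=7, dropout=0.3, random_state=5)
    cloned = clone(clf)
    assert cloned.get_params() == clf.get_params()
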