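"""Perceptron forward pass, parameter flattening, herd-search training."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from graftsurv.abo import ABOConfig
from graftsurv.ann import (
    NetworkArch,
    NetworkParams,
    default_arch,
    flatten_params,
    forward,
    forward_batch,
    n_params,
    predict,
    predict_proba,
    train_with_abo,
    unflatten_params,
)
from graftsurv.errors import ConfigurationError, DataError


def _params(arch, vec=None, rng=None):
    if vec is None:
        vec = (rng or np.random.default_rng(0)).normal(size=n_params(arch))
    return unflatten_params(np.asarray(vec, dtype=float), arch)


# -- forward pass ------------------------------------------------------------


def test_zero_weights_logistic_output_is_half():
    arch = NetworkArch(n_inputs=4, n_hidden=3)
    params = _params(arch, np.zeros(n_params(arch)))
    for x in (np.zeros(4), np.ones(4), np.array([2.0, -1.0, 0.5, 3.0])):
        assert forward(params, x) == pytest.approx(0.5)


def test_single_tanh_node_at_origin_is_zero():
    arch = NetworkArch(1, 1, hidden_activation="tanh", output_function="linear")
    params = NetworkParams(
        hidden_intercepts=np.array([0.0]),
        hidden_weights=np.array([[1.0]]),
        output_bias=0.0,
        output_weights=np.array([1.0]),
        arch=arch,
    )
    assert forward(params, np.array([0.0])) == pytest.approx(0.0)


def test_linear_network_collapses_to_affine_map(rng):
    """f'=g'=linear makes the network an affine function; check on 100 cases."""
    arch = NetworkArch(3, 4, hidden_activation="linear", output_function="linear")
    params = _params(arch, rng=rng)
    # composed affine map: s = a + b^T (m + W x) = (a + b^T m) + (b^T W) x
    w_eff = params.output_weights @ params.hidden_weights
    b_eff = params.output_bias + params.output_weights @ params.hidden_intercepts
    for _ in range(100):
        x = rng.normal(size=3)
        assert forward(params, x) == pytest.approx(b_eff + w_eff @ x, abs=1e-12)


def test_forward_dimension_mismatch_errors():
    arch = NetworkArch(3, 2)
    params = _params(arch, np.zeros(n_params(arch)))
    with pytest.raises(ConfigurationError):
        forward(params, np.zeros(5))


def test_invalid_activation_names_rejected():
    with pytest.raises(ConfigurationError):
        NetworkArch(2, 2, hidden_activation="relu")
    with pytest.raises(ConfigurationError):
        NetworkArch(2, 2, output_function="tanh")


# -- flattening --------------------------------------------------------------


def test_param_vector_length_counts_all_weights():
    arch = NetworkArch(n_inputs=2, n_hidden=3)
    assert n_params(arch) == 3 + 6 + 1 + 3


def test_zero_vector_gives_all_zero_params():
    arch = NetworkArch(2, 2)
    params = unflatten_params(np.zeros(n_params(arch)), arch)
    assert (params.hidden_weights == 0).all()
    assert (params.hidden_intercepts == 0).all()
    assert params.output_bias == 0.0
    assert (params.output_weights == 0).all()


def test_wrong_vector_length_rejected():
    with pytest.raises(ConfigurationError):
        unflatten_params(np.zeros(5), NetworkArch(2, 3))


@given(st.integers(1, 5), st.integers(1, 6), st.integers(0, 1000))
def test_flatten_round_trip_is_exact(p, h, seed):
    arch = NetworkArch(n_inputs=p, n_hidden=h)
    vec = np.random.default_rng(seed).normal(size=n_params(arch))
    params = unflatten_params(vec, arch)
    np.testing.assert_array_equal(flatten_params(params), vec)


# -- training ----------------------------------------------------------------


def _two_clusters(seed, n=200):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(loc=[-2.0, -2.0], scale=0.5, size=(half, 2)),
            rng.normal(loc=[2.0, 2.0], scale=0.5, size=(half, 2)),
        ]
    )
    y = np.r_[np.zeros(half), np.ones(half)]
    return X, y


def test_training_reaches_high_accuracy_on_separable_clusters():
    hits = 0
    for seed in range(10):
        X, y = _two_clusters(seed)
        model = train_with_abo(X, y, abo_config=ABOConfig(seed=seed))
        acc = float(np.mean(predict(model, X) == y))
        hits += acc >= 0.95
    assert hits >= 9


def test_label_flip_symmetry_on_symmetric_architecture():
    X, y = _two_clusters(42)
    m1 = train_with_abo(X, y, abo_config=ABOConfig(seed=0))
    m2 = train_with_abo(X, 1 - y, abo_config=ABOConfig(seed=0))
    acc1 = float(np.mean(predict(m1, X) == y))
    acc2 = float(np.mean(predict(m2, X) == (1 - y)))
    assert abs(acc1 - acc2) <= 0.05


def test_returned_objective_no_worse_than_initial_herd():
    from graftsurv.abo import init_herd
    from graftsurv.ann import _training_objective

    X, y = _two_clusters(7)
    cfg = ABOConfig(seed=7, max_iterations=50)
    model = train_with_abo(X, y, abo_config=cfg)
    arch = model.params.arch
    Xs = model.standardize(X)
    obj = _training_objective("mse", Xs, y, arch)
    from graftsurv.ann import n_params as npar

    herd0 = init_herd(obj, npar(arch), cfg)
    assert model.objective_value <= herd0.bg_f + 1e-12


def test_last_layer_scope_trains_output_weights_only():
    X, y = _two_clusters(3)
    model = train_with_abo(
        X, y, scope="last_layer", abo_config=ABOConfig(seed=3)
    )
    acc = float(np.mean(predict(model, X) == y))
    assert acc >= 0.9


def test_single_class_labels_rejected():
    X = np.random.default_rng(0).normal(size=(20, 2))
    with pytest.raises(DataError):
        train_with_abo(X, np.ones(20))


def test_misclassification_objective_accepted():
    X, y = _two_clusters(5, n=80)
    model = train_with_abo(
        X, y, objective="misclassification",
        abo_config=ABOConfig(seed=5, max_iterations=60),
    )
    assert float(np.mean(predict(model, X) == y)) >= 0.9


def test_standardizer_comes_from_training_rows_only():
    X, y = _two_clusters(1)
    model = train_with_abo(X, y, abo_config=ABOConfig(seed=1, max_iterations=20))
    np.testing.assert_allclose(model.x_mean, X.mean(axis=0))
    np.testing.assert_allclose(model.x_std, X.std(axis=0))
    shifted = X + 100.0  # test rows must reuse the training statistics
    np.testing.assert_allclose(
        model.standardize(shifted), model.standardize(X) + 100.0 / model.x_std
    )


# -- prediction --------------------------------------------------------------


def test_probabilities_in_unit_interval_and_boundary_is_positive():
    X, y = _two_clusters(2, n=60)
    model = train_with_abo(X, y, abo_config=ABOConfig(seed=2, max_iterations=30))
    proba = predict_proba(model, X)
    assert ((proba >= 0) & (proba <= 1)).all()
    # s >= cutoff convention at the boundary
    arch = NetworkArch(1, 1)
    flat = np.zeros(n_params(arch))
    params = unflatten_params(flat, arch)
    from graftsurv.ann import TrainedNetwork

    m = TrainedNetwork(
        params=params, x_mean=np.zeros(1), x_std=np.ones(1),
        history=np.array([]),
    )
    assert predict(m, np.array([[0.0]]), cutoff=0.5)[0] == 1  # s = 0.5 exactly


def test_raising_cutoff_never_increases_positives():
    X, y = _two_clusters(6, n=100)
    model = train_with_abo(X, y, abo_config=ABOConfig(seed=6, max_iterations=30))
    pos = [predict(model, X, cutoff=c).sum() for c in (0.3, 0.5, 0.7, 0.9)]
    assert pos == sorted(pos, reverse=True)


def test_predict_proba_requires_logistic_output():
    arch = NetworkArch(2, 2, output_function="linear")
    params = _params(arch, np.zeros(n_params(arch)))
    from graftsurv.ann import TrainedNetwork

    m = TrainedNetwork(
        params=params, x_mean=np.zeros(2), x_std=np.ones(2), history=np.array([])
    )
    with pytest.raises(ConfigurationError):
        predict_proba(m, np.zeros((1, 2)))


def test_model_json_round_trip(tmp_path):
    from graftsurv.ann import TrainedNetwork

    X, y = _two_clusters(4, n=60)
    model = train_with_abo(X, y, abo_config=ABOConfig(seed=4, max_iterations=20))
    model.to_json(tmp_path / "m.json")
    back = TrainedNetwork.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(predict_proba(back, X), predict_proba(model, X))


def test_default_arch_hidden_size_rule():
    assert default_arch(4).n_hidden == 3
    assert default_arch(36).n_hidden == 6
    assert default_arch(50).n_hidden == 8
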