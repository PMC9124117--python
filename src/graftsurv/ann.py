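"""Single-hidden-layer perceptron trained by the buffalo-herd optimizer.

The network is the classical feed-forward form

    t_n = f'(m_n + sum_p mu_np * l_p)          (hidden node n)
    s   = g'(a + sum_n b_n * t_n)              (network output)

with hidden activation f' and output function g' drawn from
{tanh, logistic, linear}. Instead of backpropagation, the flattened weight
vector (hidden intercepts, hidden weights row-major, output bias, output
weights) is searched by :func:`graftsurv.abo.minimize` over a bounded box,
minimizing the mean squared error between the output s and the 0/1 survival
label (misclassification rate is available as an alternative fitness).

Covariates are standardized to zero mean / unit variance using statistics
from the training rows only; the fitted scaler travels with the trained
network and is reused verbatim at prediction time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import abo
from .errors import ConfigurationError, DataError

__all__ = [
    "NetworkArch",
    "NetworkParams",
    "TrainedNetwork",
    "forward",
    "forward_batch",
    "n_params",
    "flatten_params",
    "unflatten_params",
    "train_with_abo",
    "predict_proba",
    "predict",
    "ANNClassifier",
]

_ACTIVATIONS = {
    "tanh": np.tanh,
    "logistic": expit,
    "linear": lambda z: z,
}


@dataclass(frozen=True)
class NetworkArch:
    """Shape and activation choices of the perceptron."""

    n_inputs: int
    n_hidden: int
    hidden_activation: str = "tanh"
    output_function: str = "logistic"

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ConfigurationError("n_inputs and n_hidden must be positive")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"hidden_activation must be one of {sorted(_ACTIVATIONS)}"
            )
        if self.output_function not in ("logistic", "linear"):
            raise ConfigurationError("output_function must be logistic or linear")


def default_arch(n_inputs: int, **kwargs) -> NetworkArch:
    """One hidden layer with max(3, ceil(sqrt(p))) nodes."""
    return NetworkArch(
        n_inputs=n_inputs, n_hidden=max(3, math.ceil(math.sqrt(n_inputs))), **kwargs
    )


@dataclass
class NetworkParams:
    """Weights of one network: intercepts, hidden weights, output layer."""

    hidden_intercepts: np.ndarray  # (n_hidden,)
    hidden_weights: np.ndarray  # (n_hidden, n_inputs)
    output_bias: float
    output_weights: np.ndarray  # (n_hidden,)
    arch: NetworkArch

    def __post_init__(self) -> None:
        h, p = self.arch.n_hidden, self.arch.n_inputs
        if self.hidden_intercepts.shape != (h,):
            raise ConfigurationError("hidden_intercepts shape mismatch")
        if self.hidden_weights.shape != (h, p):
            raise ConfigurationError("hidden_weights shape mismatch")
        if self.output_weights.shape != (h,):
            raise ConfigurationError("output_weights shape mismatch")


def n_params(arch: NetworkArch) -> int:
    """Flattened parameter-vector length: h + h*p + 1 + h."""
    return arch.n_hidden * (arch.n_inputs + 2) + 1


def flatten_params(params: NetworkParams) -> np.ndarray:
    """Fixed ordering: intercepts, hidden weights row-major, bias, output weights."""
    return np.concatenate(
        [
            params.hidden_intercepts,
            params.hidden_weights.ravel(),
            [params.output_bias],
            params.output_weights,
        ]
    )


def unflatten_params(vector: np.ndarray, arch: NetworkArch) -> NetworkParams:
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (n_params(arch),):
        raise ConfigurationError(
            f"expected vector of length {n_params(arch)}, got {vector.shape}"
        )
    h, p = arch.n_hidden, arch.n_inputs
    intercepts = vector[:h]
    weights = vector[h : h + h * p].reshape(h, p)
    bias = float(vector[h + h * p])
    out_w = vector[h + h * p + 1 :]
    return NetworkParams(
        hidden_intercepts=intercepts.copy(),
        hidden_weights=weights.copy(),
        output_bias=bias,
        output_weights=out_w.copy(),
        arch=arch,
    )


def forward_batch(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Network output s for every row of X (no standardization applied)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.arch.n_inputs:
        raise ConfigurationError(
            f"expected {params.arch.n_inputs} covariates, got {X.shape[1]}"
        )
    f_h = _ACTIVATIONS[params.arch.hidden_activation]
    g = _ACTIVATIONS[params.arch.output_function]
    t = f_h(params.hidden_intercepts[None, :] + X @ params.hidden_weights.T)
    return g(params.output_bias + t @ params.output_weights)


def forward(params: NetworkParams, x: np.ndarray) -> float:
    """Output s for a single covariate vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("forward expects a 1-d covariate vector")
    return float(forward_batch(params, x[None, :])[0])


@dataclass
class TrainedNetwork:
    """A fitted network: weights plus the training-time standardizer."""

    params: NetworkParams
    x_mean: np.ndarray
    x_std: np.ndarray
    history: np.ndarray = field(repr=False)
    objective_value: float = np.nan

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean[None, :]) / self.x_std[None, :]

    # -- text serialization ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        a = self.params.arch
        payload = {
            "arch": {
                "n_inputs": a.n_inputs,
                "n_hidden": a.n_hidden,
                "hidden_activation": a.hidden_activation,
                "output_function": a.output_function,
            },
            "flat_params": list(map(float, flatten_params(self.params))),
            "x_mean": list(map(float, self.x_mean)),
            "x_std": list(map(float, self.x_std)),
            "objective_value": float(self.objective_value),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedNetwork":
        payload = json.loads(Path(path).read_text())
        arch = NetworkArch(**payload["arch"])
        params = unflatten_params(np.array(payload["flat_params"]), arch)
        return cls(
            params=params,
            x_mean=np.array(payload["x_mean"]),
            x_std=np.array(payload["x_std"]),
            history=np.array([]),
            objective_value=payload["objective_value"],
        )


def _training_objective(
    kind: str, X: np.ndarray, y: np.ndarray, arch: NetworkArch
):
    if kind == "mse":

        def obj(vec: np.ndarray) -> float:
            s = forward_batch(unflatten_params(vec, arch), X)
            return float(np.mean((s - y) ** 2))

    elif kind == "misclassification":

        def obj(vec: np.ndarray) -> float:
            s = forward_batch(unflatten_params(vec, arch), X)
            return float(np.mean((s >= 0.5).astype(int) != y))

    else:
        raise ConfigurationError("objective must be 'mse' or 'misclassification'")
    return obj


def train_with_abo(
    X: np.ndarray,
    y: np.ndarray,
    arch: NetworkArch | None = None,
    abo_config: abo.ABOConfig | None = None,
    scope: str = "all_weights",
    objective: str = "mse",
) -> TrainedNetwork:
    """Fit the perceptron by herd search over its weight vector.

    ``scope="all_weights"`` searches every parameter; ``scope="last_layer"``
    freezes random hidden weights (a random-projection hidden layer) and
    searches only the output bias and output weights.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ConfigurationError("X and y must have equal length")
    if len(X) == 0:
        raise DataError("empty training data")
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("training labels contain a single class")
    if scope not in ("all_weights", "last_layer"):
        raise ConfigurationError("scope must be all_weights or last_layer")

    if arch is None:
        arch = default_arch(X.shape[1])
    if abo_config is None:
        abo_config = abo.ABOConfig(bounds=(-5.0, 5.0))

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std[x_std == 0] = 1.0
    Xs = (X - x_mean[None, :]) / x_std[None, :]

    if scope == "all_weights":
        obj = _training_objective(objective, Xs, y, arch)
        dims = n_params(arch)
        result = abo.minimize(obj, dims, abo_config)
        params = unflatten_params(result.best_x, arch)
    else:
        rng = np.random.default_rng(abo_config.seed)
        hidden_w = rng.normal(scale=1.0 / math.sqrt(arch.n_inputs),
                              size=(arch.n_hidden, arch.n_inputs))
        hidden_b = rng.normal(size=arch.n_hidden)
        inner = _training_objective(objective, Xs, y, arch)

        def obj(vec: np.ndarray) -> float:
            full = np.concatenate([hidden_b, hidden_w.ravel(), vec])
            return inner(full)

        dims = 1 + arch.n_hidden
        result = abo.minimize(obj, dims, abo_config)
        params = unflatten_params(
            np.concatenate([hidden_b, hidden_w.ravel(), result.best_x]), arch
        )
    return TrainedNetwork(
        params=params,
        x_mean=x_mean,
        x_std=x_std,
        history=result.history,
        objective_value=result.best_f,
    )


def predict_proba(model: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Survival probabilities; requires a logistic output function."""
    if model.params.arch.output_function != "logistic":
        raise ConfigurationError(
            "predict_proba requires output_function='logistic'"
        )
    return forward_batch(model.params, model.standardize(X))


def predict(model: TrainedNetwork, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Hard labels: class 1 ('survive') iff the output s >= cutoff."""
    s = forward_batch(model.params, model.standardize(X))
    return (s >= cutoff).astype(int)


class ANNClassifier:
    """Minimal scikit-learn-style wrapper, usable inside wrapper selection.

    Defaults use a reduced herd budget so that subset-search loops that
    refit the classifier hundreds of times stay tractable.
    """

    def __init__(
        self,
        arch: NetworkArch | None = None,
        abo_config: abo.ABOConfig | None = None,
        scope: str = "all_weights",
        objective: str = "mse",
        cutoff: float = 0.5,
        random_state: int = 0,
    ):
        self.arch = arch
        self.abo_config = abo_config
        self.scope = scope
        self.objective = objective
        self.cutoff = cutoff
        self.random_state = random_state
        self.model_: TrainedNetwork | None = None

    def fit(self, X, y):
        cfg = self.abo_config
        if cfg is None:
            cfg = abo.ABOConfig(
                n_buffalo=10, max_iterations=40, bounds=(-5.0, 5.0),
                seed=self.random_state,
            )
        self.model_ = train_with_abo(
            np.asarray(X), np.asarray(y), arch=self.arch, abo_config=cfg,
            scope=self.scope, objective=self.objective,
        )
        return self

    def predict(self, X):
        if self.model_ is None:
            raise ConfigurationError("classifier is not fitted")
        return predict(self.model_, np.asarray(X), cutoff=self.cutoff)

    def predict_proba_1(self, X):
        if self.model_ is None:
            raise ConfigurationError("classifier is not fitted")
        return predict_proba(self.model_, np.asarray(X))
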