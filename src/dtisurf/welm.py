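"""Weighted extreme learning machine with closed-form ridge training.

A single-hidden-layer feedforward network whose hidden layer is random
and fixed: input weights a_h ~ U(-1, 1) and biases b_h ~ U(0, 1) are
drawn once, and only the output weights beta are learned, by regularised
least squares on the hidden activations H (``H beta = T``).  With N
training samples and L hidden neurons the ridge solution has two
algebraically equivalent closed forms,

    beta = H^T (I/C + W H H^T)^{-1} W T          (N < L)
    beta = (I/C + H^T W H)^{-1} H^T W T          (N >= L)

where C is the ridge parameter and W a diagonal per-sample weight
matrix that counters class imbalance.  Two weighting strategies are
provided: ``w1`` gives every sample of class t weight 1/Count(t)
(automatic rebalancing), and ``w2`` additionally discounts the majority
class by the golden ratio, 0.618/Count(t) for the majority versus
1/Count(t) for the minority.  ``strategy="none"`` (W = I) is the plain
unweighted ELM baseline.

Targets are one-hot in {-1, +1}; prediction decodes by argmax over the
class score columns.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import linalg

GOLDEN_RATIO = 0.618

_ACTIVATIONS = ("sigmoid", "gaussian")
_STRATEGIES = ("none", "w1", "w2")


@dataclass(frozen=True)
class WELMConfig:
    """Model hyper-parameters; defaults follow the reference protocol
    (2500 sigmoid hidden neurons, C = 160, automatic weighting)."""

    n_hidden: int = 2500
    activation: str = "sigmoid"
    C: float = 160.0
    strategy: str = "w1"
    seed: int = 0
    # column indices to z-score with training statistics (None = no scaling)
    scale_cols: tuple | None = None

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.C <= 0:
            raise ValueError("ridge parameter C must be positive")


@dataclass
class HiddenLayer:
    """Random, fixed hidden layer: weights, biases and activation name."""

    input_weights: np.ndarray  # (n_hidden, input_dim)
    biases: np.ndarray  # (n_hidden,)
    activation: str
    seed: int


@dataclass
class WELMModel:
    hidden: HiddenLayer
    beta: np.ndarray  # (n_hidden, n_classes)
    config: WELMConfig
    class_order: tuple
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None


# ---------------------------------------------------------------------------
# hidden layer
# ---------------------------------------------------------------------------


def init_hidden_layer(
    input_dim: int,
    n_hidden: int = 2500,
    activation: str = "sigmoid",
    seed: int = 0,
) -> HiddenLayer:
    """Draw the random hidden layer: weights U(-1, 1), biases U(0, 1)."""
    if n_hidden < 1:
        raise ValueError("need at least one hidden neuron")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-1.0, 1.0, size=(n_hidden, input_dim))
    biases = rng.uniform(0.0, 1.0, size=n_hidden)
    return HiddenLayer(weights, biases, activation, seed)


def hidden_matrix(X: np.ndarray, layer: HiddenLayer) -> np.ndarray:
    """Hidden activations H (samples x n_hidden).

    sigmoid:  H_ij = 1 / (1 + exp(-(a_j . x_i + b_j)))
    gaussian: H_ij = exp(-b_j ||x_i - a_j||^2)   (RBF nodes with the
    weight rows as centres and biases as widths)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.input_weights.shape[1]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match hidden layer "
            f"({layer.input_weights.shape[1]})"
        )
    if layer.activation == "sigmoid":
        Z = X @ layer.input_weights.T + layer.biases
        return 1.0 / (1.0 + np.exp(-Z))
    sq = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ layer.input_weights.T
        + (layer.input_weights**2).sum(axis=1)[None, :]
    )
    return np.exp(-layer.biases[None, :] * np.maximum(sq, 0.0))


# ---------------------------------------------------------------------------
# class weights and the closed-form solve
# ---------------------------------------------------------------------------


def class_weights(labels: Sequence, strategy: str) -> np.ndarray:
    """Per-sample diagonal of W for the two rebalancing strategies.

    ``w1``: 1/Count(class of sample).  ``w2``: the golden-ratio split —
    0.618/Count for the (unique) majority class, 1/Count otherwise; when
    class sizes tie there is no majority and every class gets the
    minority weight.
    """
    if strategy not in ("w1", "w2"):
        raise ValueError(f"unknown weighting strategy {strategy!r}")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("class weighting needs at least two classes")
    weight_of = {}
    majority = classes[counts.argmax()] if (counts == counts.max()).sum() == 1 else None
    for cls, count in zip(classes, counts):
        w = 1.0 / count
        if strategy == "w2" and majority is not None and cls == majority:
            w = GOLDEN_RATIO / count
        weight_of[cls] = w
    return np.array([weight_of[lbl] for lbl in labels])


def solve_output_weights(
    H: np.ndarray,
    T: np.ndarray,
    weights: np.ndarray | None = None,
    C: float = 160.0,
) -> np.ndarray:
    """Closed-form ridge output weights; branch picked by N < L vs N >= L.

    ``weights`` is the diagonal of W (None = unweighted).  The two
    branches are related by the push-through identity and agree to
    numerical precision; solves go through an LU factorisation of the
    regularised Gram matrix rather than explicit inversion.
    """
    if C <= 0:
        raise ValueError("ridge parameter C must be positive")
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if T.shape[0] != H.shape[0]:
        raise ValueError("H and T row counts differ")
    if not (np.isfinite(H).all() and np.isfinite(T).all()):
        raise ValueError("non-finite entries in H or T")
    N, L = H.shape
    if weights is None:
        w = np.ones(N)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (N,):
            raise ValueError("weights must be one value per sample")
    if N < L:
        A = np.eye(N) / C + w[:, None] * (H @ H.T)  # I/C + W H H^T
        return H.T @ linalg.solve(A, w[:, None] * T)
    A = np.eye(L) / C + H.T @ (w[:, None] * H)  # I/C + H^T W H
    return linalg.solve(A, H.T @ (w[:, None] * T))


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------


def _one_hot(labels: np.ndarray, class_order: tuple) -> np.ndarray:
    T = -np.ones((labels.shape[0], len(class_order)))
    for j, cls in enumerate(class_order):
        T[labels == cls, j] = 1.0
    return T


def _apply_scaling(model: WELMModel, X: np.ndarray) -> np.ndarray:
    if model.scale_mean is None:
        return X
    X = np.array(X, dtype=float)
    cols = list(model.config.scale_cols)
    X[:, cols] = (X[:, cols] - model.scale_mean) / model.scale_std
    return X


def fit(X: np.ndarray, labels: Sequence, config: WELMConfig = WELMConfig()) -> WELMModel:
    """Train a (weighted) ELM: draw the hidden layer, solve for beta.

    Columns named in ``config.scale_cols`` are z-scored with statistics
    of this training set (stored on the model so prediction applies the
    same transform); remaining columns — e.g. binary fingerprint bits —
    pass through untouched.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] < 2:
        raise ValueError("need at least two training samples")
    class_order = tuple(np.unique(labels).tolist())
    if len(class_order) < 2:
        raise ValueError("training labels contain a single class")
    scale_mean = scale_std = None
    if config.scale_cols is not None:
        cols = list(config.scale_cols)
        scale_mean = X[:, cols].mean(axis=0)
        scale_std = X[:, cols].std(axis=0)
        scale_std = np.where(scale_std > 0, scale_std, 1.0)
        X = np.array(X)
        X[:, cols] = (X[:, cols] - scale_mean) / scale_std
    layer = init_hidden_layer(X.shape[1], config.n_hidden, config.activation, config.seed)
    H = hidden_matrix(X, layer)
    T = _one_hot(labels, class_order)
    w = None if config.strategy == "none" else class_weights(labels, config.strategy)
    beta = solve_output_weights(H, T, weights=w, C=config.C)
    return WELMModel(layer, beta, config, class_order, scale_mean, scale_std)


def decision_scores(model: WELMModel, X: np.ndarray) -> np.ndarray:
    """Real-valued class scores f(x) = h(x) beta (samples x n_classes).

    The column of the positive class is the ranking score for ROC
    analysis.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X = _apply_scaling(model, X)
    return hidden_matrix(X, model.hidden) @ model.beta


def predict(model: WELMModel, X: np.ndarray) -> np.ndarray:
    """Argmax decode of the class scores; ties go to the earlier class."""
    scores = decision_scores(model, X)
    idx = scores.argmax(axis=1)
    return np.array([model.class_order[i] for i in idx])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: WELMModel, path) -> None:
    """Serialise a fitted model to a single ``.npz`` archive."""
    meta = {
        "config": asdict(model.config),
        "class_order": list(model.class_order),
        "activation": model.hidden.activation,
        "seed": model.hidden.seed,
    }
    arrays = {
        "input_weights": model.hidden.input_weights,
        "biases": model.hidden.biases,
        "beta": model.beta,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if model.scale_mean is not None:
        arrays["scale_mean"] = model.scale_mean
        arrays["scale_std"] = model.scale_std
    np.savez(path, **arrays)


def load_model(path) -> WELMModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        cfg = meta["config"]
        if cfg.get("scale_cols") is not None:
            cfg["scale_cols"] = tuple(cfg["scale_cols"])
        config = WELMConfig(**cfg)
        layer = HiddenLayer(
            npz["input_weights"], npz["biases"], meta["activation"], meta["seed"]
        )
        return WELMModel(
            hidden=layer,
            beta=npz["beta"],
            config=config,
            class_order=tuple(meta["class_order"]),
            scale_mean=npz["scale_mean"] if "scale_mean" in npz else None,
            scale_std=npz["scale_std"] if "scale_std" in npz else None,
        )
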