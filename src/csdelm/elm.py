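"""Single extreme learning machine (ELM).

An ELM is a single-hidden-layer feedforward network whose hidden-layer
parameters — input weights ``a_j`` and biases ``b_j`` — are drawn once at
random and frozen.  Only the linear output layer ``beta`` is fitted, as the
minimum-norm least-squares solution against one-hot class targets, so
training reduces to a single pseudoinverse solve.  That one-step fit is
what makes large voting ensembles of ELMs cheap to train.

Conventions used throughout:

* hidden parameters are i.i.d. uniform on [-1, 1] (the convention of the
  ELM literature; no other distribution is assumed anywhere);
* class targets are one-hot (1 for the true class, 0 elsewhere) and
  predictions decode by argmax over score columns, ties going to the
  lowest class index, so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ELMModel",
    "init_elm",
    "hidden_output",
    "fit_output_weights",
    "train_elm",
    "predict_scores",
    "predict_labels",
    "one_hot",
    "ordered_classes",
    "ACTIVATIONS",
]

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMModel:
    """One single-hidden-layer network with random, frozen hidden layer.

    Attributes
    ----------
    input_weights : ndarray of shape (L, p)
        Row ``j`` is the input-weight vector ``a_j`` of hidden node ``j``.
    biases : ndarray of shape (L,)
        Hidden-node biases ``b_j``.
    activation : str
        One of ``"sigmoid"``, ``"tanh"``, ``"relu"``.
    hidden_size : int
        Number of hidden nodes ``L``.
    classes : list or None
        Ordered class vocabulary; set when the model is trained.
    output_weights : ndarray of shape (L, m) or None
        Fitted output weights ``beta``; ``None`` until trained.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    activation: str
    hidden_size: int
    classes: list | None = None
    output_weights: np.ndarray | None = None

    @property
    def feature_dim(self) -> int:
        return self.input_weights.shape[1]

    @property
    def is_trained(self) -> bool:
        return self.output_weights is not None


def init_elm(
    feature_dim: int,
    hidden_size: int,
    activation: str = "sigmoid",
    rng: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> ELMModel:
    """Draw the random hidden layer of an untrained ELM.

    Input weights and biases are i.i.d. uniform on [-1, 1]; the same seed
    yields bit-identical parameters.  The output layer is left unset.
    """
    if int(feature_dim) < 1:
        raise ValueError(f"feature_dim must be >= 1, got {feature_dim}")
    if int(hidden_size) < 1:
        raise ValueError(f"hidden_size must be >= 1, got {hidden_size}")
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}"
        )
    gen = np.random.default_rng(rng)
    weights = gen.uniform(-1.0, 1.0, size=(int(hidden_size), int(feature_dim)))
    biases = gen.uniform(-1.0, 1.0, size=int(hidden_size))
    return ELMModel(
        input_weights=weights,
        biases=biases,
        activation=activation,
        hidden_size=int(hidden_size),
    )


def hidden_output(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix H with H[k, j] = g(a_j . x_k + b_j)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got ndim={X.ndim}")
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"X has {X.shape[1]} features but model expects {model.feature_dim}"
        )
    g = ACTIVATIONS[model.activation]
    return g(X @ model.input_weights.T + model.biases)


def fit_output_weights(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights ``beta = H^+ T``.

    Uses the SVD-based pseudoinverse solve (``numpy.linalg.lstsq`` with the
    default numerical rank tolerance); no ridge term is added.  Among all
    matrices ``beta'``, the returned ``beta`` minimises the Frobenius
    residual ``||H beta - T||_F``.
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if H.ndim != 2 or H.size == 0:
        raise ValueError("H must be a nonempty 2-D matrix")
    if T.ndim != 2:
        raise ValueError("T must be 2-D (one column per class)")
    if H.shape[0] != T.shape[0]:
        raise ValueError(
            f"H has {H.shape[0]} rows but T has {T.shape[0]}"
        )
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


def ordered_classes(y) -> list:
    """Class vocabulary in order of first appearance."""
    seen: dict = {}
    for label in y:
        if label not in seen:
            seen[label] = None
    return list(seen)


def one_hot(y, classes: list) -> np.ndarray:
    """One-hot target matrix, one column per entry of ``classes``."""
    index = {c: i for i, c in enumerate(classes)}
    T = np.zeros((len(y), len(classes)))
    for k, label in enumerate(y):
        try:
            T[k, index[label]] = 1.0
        except KeyError:
            raise ValueError(f"label {label!r} not in class vocabulary {classes}")
    return T


def train_elm(model: ELMModel, X: np.ndarray, y, classes: list | None = None) -> ELMModel:
    """Fit the output layer of ``model`` in place and return it.

    ``classes`` fixes the column order of the one-hot targets; by default
    it is the order of first appearance in ``y``.
    """
    if classes is None:
        classes = ordered_classes(y)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    H = hidden_output(model, X)
    T = one_hot(y, classes)
    model.output_weights = fit_output_weights(H, T)
    model.classes = list(classes)
    return model


def predict_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs ``hidden_output(model, X) @ beta`` (n x m)."""
    if not model.is_trained:
        raise RuntimeError("model has no output weights; train it first")
    return hidden_output(model, X) @ model.output_weights


def predict_labels(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Argmax-decoded class labels; ties go to the lowest class index."""
    scores = predict_scores(model, X)
    idx = np.argmax(scores, axis=1)
    return np.asarray([model.classes[i] for i in idx], dtype=object)
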