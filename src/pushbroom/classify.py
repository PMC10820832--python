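"""MLP spectral classifier: training, node arithmetic, and evaluation.

The classifier is a multilayer perceptron with a single 25-node hidden
layer: rectified-linear activation in the hidden layer, a logistic sigmoid
on the single output node, trained with the adam optimizer (binary
cross-entropy, at most 500 iterations). Each node computes

    y = g( sum_i w_i x_i + bias ),

with g the layer's activation. Training is delegated to scikit-learn's
MLPClassifier with those settings; the fitted weights are extracted into a
plain, JSON-serializable model whose forward pass is implemented here, so
trained models can be stored, diffed, and run without the training stack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = [
    "LabeledDataset",
    "MLPModel",
    "EvalReport",
    "split_counts",
    "split_indices",
    "node_output",
    "relu",
    "logistic",
    "train",
    "evaluate",
]

CLASS_NAMES = ("class_A", "class_B")  # 0 = lettuce-like, 1 = arugula-like


@dataclass
class LabeledDataset:
    """Feature matrix plus binary class labels (0 = A, 1 = B)."""

    X: np.ndarray
    y: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have matching first dimension")

    def __len__(self) -> int:
        return self.y.size

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.provenance)


def split_counts(total: int, train_frac: float = 0.7) -> tuple[int, int]:
    """Train/test sizes for a fractional split.

    The test set takes the ceiling of its fraction:
    ``test = ceil((1 - train_frac) * total)``, the remainder trains.
    (296,862 spectra at 0.7 give 207,803 / 89,059.)
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train fraction must lie in (0, 1)")
    if total < 2:
        raise ValueError("need at least 2 samples to split")
    # round away float noise before the ceiling (0.3*10 == 3.0000000000000004)
    test = int(math.ceil(round((1.0 - train_frac) * total, 9)))
    return total - test, test


def split_indices(
    n: int, train_frac: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random, non-stratified train/test index split."""
    n_train, _ = split_counts(n, train_frac)
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:]


def relu(z):
    return np.maximum(z, 0.0)


def logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


_ACTIVATIONS = {"relu": relu, "logistic": logistic, "identity": lambda z: z}


def node_output(x, w, bias: float, g="relu") -> float:
    """Single-node response y = g(sum_i w_i x_i + bias)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError("input and weight vectors must have the same shape")
    act = _ACTIVATIONS[g] if isinstance(g, str) else g
    return float(act(float(np.dot(w, x)) + bias))


@dataclass
class MLPModel:
    """Fitted 50 -> 25 -> 1 perceptron with JSON round-tripping."""

    hidden_weights: np.ndarray   # (input_dim, 25)
    hidden_biases: np.ndarray    # (25,)
    output_weights: np.ndarray   # (25, 1)
    output_bias: float
    hidden_activation: str = "relu"
    output_activation: str = "logistic"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        if self.hidden_weights.shape[1] != self.hidden_biases.size:
            raise ValueError("hidden layer width mismatch")
        if self.output_weights.shape != (self.hidden_biases.size, 1):
            raise ValueError("output layer shape mismatch")
        for arr in (self.hidden_weights, self.hidden_biases, self.output_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")

    @property
    def input_dim(self) -> int:
        return self.hidden_weights.shape[0]

    def predict_proba(self, X) -> np.ndarray:
        """P(class B) per sample via the explicit forward pass."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} features, got {X.shape[1]}")
        h = _ACTIVATIONS[self.hidden_activation](
            X @ self.hidden_weights + self.hidden_biases)
        z = h @ self.output_weights + self.output_bias
        return _ACTIVATIONS[self.output_activation](z).ravel()

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def to_json(self) -> str:
        return json.dumps({
            "input_dim": self.input_dim,
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "training_meta": self.training_meta,
        })

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            hidden_weights=np.array(d["hidden_weights"]),
            hidden_biases=np.array(d["hidden_biases"]),
            output_weights=np.array(d["output_weights"]),
            output_bias=float(d["output_bias"]),
            hidden_activation=d.get("hidden_activation", "relu"),
            output_activation=d.get("output_activation", "logistic"),
            training_meta=d.get("training_meta", {}),
        )


def train(
    data: LabeledDataset,
    seed: int = 0,
    max_iter: int = 500,
    hidden_nodes: int = 25,
    batch_size: int = 200,
    learning_rate: float = 1e-3,
) -> MLPModel:
    """Fit the one-hidden-layer perceptron with adam.

    Reproducible for a fixed seed. Raises on single-class data or
    non-finite features.
    """
    if not np.all(np.isfinite(data.X)):
        raise ValueError("features must be finite")
    if np.unique(data.y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_nodes,),
        activation="relu",
        solver="adam",
        max_iter=max_iter,
        random_state=seed,
        batch_size=min(batch_size, len(data)),
        learning_rate_init=learning_rate,
    )
    clf.fit(data.X, data.y)
    return MLPModel(
        hidden_weights=clf.coefs_[0],
        hidden_biases=clf.intercepts_[0],
        output_weights=clf.coefs_[1],
        output_bias=float(clf.intercepts_[1][0]),
        training_meta={
            "optimizer": "adam",
            "max_iter": max_iter,
            "n_iter": int(clf.n_iter_),
            "seed": seed,
            "final_loss": float(clf.loss_),
            "n_train": len(data),
        },
    )


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics.

    Per-class precision/recall/F-measure are NaN — flagged undefined — when
    the corresponding denominator is empty, never silently zero.
    """

    confusion_matrix: np.ndarray
    precision: tuple[float, float]
    recall: tuple[float, float]
    f_measure: tuple[float, float]
    accuracy: float

    def to_dict(self) -> dict:
        def clean(t):
            return [None if (isinstance(v, float) and math.isnan(v)) else v
                    for v in t]
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "classes": list(CLASS_NAMES),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f_measure": clean(self.f_measure),
            "accuracy": self.accuracy,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(model: MLPModel, test: LabeledDataset,
             threshold: float = 0.5) -> EvalReport:
    """Confusion matrix, per-class precision/recall/F, and accuracy."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(test.X, threshold=threshold)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(test.y, pred):
        cm[t, p] += 1
    precision = tuple(_safe_div(cm[k, k], cm[:, k].sum()) for k in (0, 1))
    recall = tuple(_safe_div(cm[k, k], cm[k, :].sum()) for k in (0, 1))
    f_measure = tuple(
        _safe_div(2.0 * precision[k] * recall[k], precision[k] + recall[k])
        if not (math.isnan(precision[k]) or math.isnan(recall[k]))
        else float("nan")
        for k in (0, 1)
    )
    return EvalReport(
        confusion_matrix=cm,
        precision=precision,  # type: ignore[arg-type]
        recall=recall,        # type: ignore[arg-type]
        f_measure=f_measure,  # type: ignore[arg-type]
        accuracy=float(np.trace(cm) / cm.sum()),
    )
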