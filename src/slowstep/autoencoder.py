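"""Single-hidden-layer sigmoid autoencoder for step feature vectors.

The network reconstructs its input through a 5-unit bottleneck,
``x' = sigmoid(W' sigmoid(W x + b) + b')``, and is trained to minimize the
mean squared reconstruction error over the training set.  One autoencoder is
fit per channel; at detection time a candidate whose feature vector the model
cannot reconstruct (low input/output Pearson correlation) is deemed unlike the
training steps.

Training is full-batch gradient descent with a backtracking line search: the
loss trace is non-increasing by construction and the whole procedure is
deterministic given the data and the initialization seed.  Transition-matrix
features already live in [0, 1]; raw-acceleration windows are min-max scaled
per dimension first (sigmoid outputs cannot leave (0, 1)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .errors import InputError

DEFAULT_HIDDEN_DIM = 5
DEFAULT_EPOCHS = 5000
DEFAULT_TOL = 1e-9
DEFAULT_LEARNING_RATE = 0.5


@dataclass
class AutoencoderModel:
    """Weights of one encoder/decoder pair plus the input scaler.

    ``scaler`` is ``(mins, maxs)`` for raw-acceleration inputs or ``None``
    (identity) for transition features, which are already in [0, 1].
    """

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (input, hidden)
    b2: np.ndarray  # (input,)
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.loss_trace = np.asarray(self.loss_trace, dtype=float)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]


def init_model(input_dim: int, hidden_dim: int = DEFAULT_HIDDEN_DIM, seed: int = 0) -> AutoencoderModel:
    """Seeded symmetric-uniform initialization, scaled by 1/sqrt(fan-in); zero biases."""
    if input_dim < 1 or hidden_dim < 1:
        raise InputError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    r1 = 1.0 / np.sqrt(input_dim)
    r2 = 1.0 / np.sqrt(hidden_dim)
    return AutoencoderModel(
        W1=rng.uniform(-r1, r1, size=(hidden_dim, input_dim)),
        b1=np.zeros(hidden_dim),
        W2=rng.uniform(-r2, r2, size=(input_dim, hidden_dim)),
        b2=np.zeros(input_dim),
    )


def reconstruct(model: AutoencoderModel, x) -> np.ndarray:
    """Forward pass; accepts one vector or a batch, entries end up in (0, 1)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    batch = x[None, :] if single else x
    if batch.shape[1] != model.input_dim:
        raise InputError(
            f"input has dimension {batch.shape[1]}, model expects {model.input_dim}"
        )
    hidden = expit(batch @ model.W1.T + model.b1)
    out = expit(hidden @ model.W2.T + model.b2)
    return out[0] if single else out


def _loss_and_grads(
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
    X: np.ndarray,
    weight_decay: float = 0.0,
) -> tuple[float, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Mean squared reconstruction error and its analytic gradients."""
    n = len(X)
    A1 = expit(X @ W1.T + b1)
    A2 = expit(A1 @ W2.T + b2)
    diff = A2 - X
    loss = float(np.sum(diff**2) / n)
    if weight_decay:
        loss += weight_decay * (float(np.sum(W1**2)) + float(np.sum(W2**2)))
    dZ2 = (2.0 / n) * diff * A2 * (1.0 - A2)
    gW2 = dZ2.T @ A1
    gb2 = dZ2.sum(axis=0)
    dZ1 = (dZ2 @ W2) * A1 * (1.0 - A1)
    gW1 = dZ1.T @ X
    gb1 = dZ1.sum(axis=0)
    if weight_decay:
        gW1 = gW1 + 2.0 * weight_decay * W1
        gW2 = gW2 + 2.0 * weight_decay * W2
    return loss, (gW1, gb1, gW2, gb2)


def _loss(W1, b1, W2, b2, X, weight_decay=0.0) -> float:
    A2 = expit(expit(X @ W1.T + b1) @ W2.T + b2)
    loss = float(np.sum((A2 - X) ** 2) / len(X))
    if weight_decay:
        loss += weight_decay * (float(np.sum(W1**2)) + float(np.sum(W2**2)))
    return loss


def train(
    X,
    hidden_dim: int = DEFAULT_HIDDEN_DIM,
    epochs: int = DEFAULT_EPOCHS,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    weight_decay: float = 0.0,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> AutoencoderModel:
    """Fit an autoencoder by full-batch gradient descent with backtracking.

    Each epoch takes the steepest-descent step, halving the step size until
    the loss does not increase, then lets it grow again; training stops at
    ``epochs`` or when the per-epoch improvement drops below ``tol``.  The
    recorded loss trace (initial loss first) is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise InputError("training set must be a non-empty (n, d) array")
    if np.any(X < -1e-12) or np.any(X > 1 + 1e-12):
        raise InputError("training vectors must be scaled to [0, 1]")
    model = init_model(X.shape[1], hidden_dim, seed)
    params = [model.W1, model.b1, model.W2, model.b2]
    lr = learning_rate
    trace = []
    loss, grads = _loss_and_grads(*params, X, weight_decay)
    trace.append(loss)
    for _ in range(epochs):
        accepted = False
        while lr >= 1e-16:
            trial = [p - lr * g for p, g in zip(params, grads)]
            new_loss = _loss(*trial, X, weight_decay)
            if new_loss <= loss:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break
        params = trial
        improvement = loss - new_loss
        loss = new_loss
        trace.append(loss)
        if improvement < tol:
            break
        _, grads = _loss_and_grads(*params, X, weight_decay)
        lr = min(lr * 1.25, 100.0)
    return AutoencoderModel(
        W1=params[0], b1=params[1], W2=params[2], b2=params[3],
        scaler=scaler, loss_trace=np.asarray(trace),
    )


def fit_scaler(X) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (min, max) over the training set."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise InputError("need a non-empty (n, d) array to fit a scaler")
    return X.min(axis=0), X.max(axis=0)


def apply_scaler(scaler: tuple[np.ndarray, np.ndarray] | None, x) -> np.ndarray:
    """Min-max map to [0, 1], clamping out-of-range values; constant dims -> 0.5.

    ``scaler=None`` is the identity (transition features already comply).
    """
    x = np.asarray(x, dtype=float)
    if scaler is None:
        return x
    mins, maxs = (np.asarray(v, dtype=float) for v in scaler)
    span = maxs - mins
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (x - mins) / np.where(span > 0, span, 1.0), 0.5)
    return np.clip(scaled, 0.0, 1.0)


def save_model(model: AutoencoderModel, path) -> Path:
    """Serialize weights, biases, scaler and loss trace to JSON (exact round-trip)."""
    path = Path(path)
    path.write_text(json.dumps(model_to_dict(model)))
    return path


def load_model(path) -> AutoencoderModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def model_to_dict(model: AutoencoderModel) -> dict:
    doc = {
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "scaler": None
        if model.scaler is None
        else [model.scaler[0].tolist(), model.scaler[1].tolist()],
        "loss_trace": model.loss_trace.tolist(),
        "input_dim": model.input_dim,
        "hidden_dim": model.hidden_dim,
    }
    return doc


def model_from_dict(doc: dict) -> AutoencoderModel:
    scaler = doc.get("scaler")
    return AutoencoderModel(
        W1=np.asarray(doc["W1"]),
        b1=np.asarray(doc["b1"]),
        W2=np.asarray(doc["W2"]),
        b2=np.asarray(doc["b2"]),
        scaler=None if scaler is None else (np.asarray(scaler[0]), np.asarray(scaler[1])),
        loss_trace=np.asarray(doc.get("loss_trace", [])),
    )
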