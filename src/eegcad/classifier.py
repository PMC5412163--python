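"""Small feed-forward neural network for two-class EEG segment classification.

Architecture: one hidden layer of 5 log-sigmoid units and a 2-unit softmax
output.  The positive ("autistic") class is output index 0.  Features are
z-scored with statistics fitted on the training data only — unnormalised
entropy magnitudes would saturate the log-sigmoid units.

Training is full-batch gradient descent with classical momentum on the mean
cross-entropy, stopping early when the epoch-to-epoch loss change falls
below a tolerance.  Everything is deterministic for a fixed seed, and with
full batches the fitted weights are independent of training-sample order up
to floating-point summation noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureVector

#: Output-unit order: index 0 is the positive (autistic) class.
CLASS_ORDER = ("autistic", "normal")

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class ANNConfig:
    hidden: int = 5
    lr: float = 0.01
    momentum: float = 0.9
    epochs: int = 500
    tol: float = 1e-6
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ANNModel:
    """Fitted weights, biases and feature-normalisation parameters."""

    W1: np.ndarray  # (hidden, n_features)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (2, hidden)
    b2: np.ndarray  # (2,)
    center: np.ndarray  # per-feature mean of the training data
    scale: np.ndarray  # per-feature std of the training data
    config: ANNConfig = field(default_factory=ANNConfig)
    loss_curve: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_matrix(features: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([fv.values for fv in features])
    y = np.array([0 if fv.label == "autistic" else 1 for fv in features])
    return X, y


def _forward(model_or_weights, Xn: np.ndarray):
    W1, b1, W2, b2 = model_or_weights
    H = _sigmoid(Xn @ W1.T + b1)
    P = _softmax(H @ W2.T + b2)
    return H, P


def train(features: Sequence[FeatureVector], config: ANNConfig | None = None) -> ANNModel:
    """Fit the network on labelled feature vectors.

    Requires at least two samples of each class and a common vector length.
    Deterministic given ``config.seed``; the recorded loss curve is
    non-increasing up to the optimiser's tolerance.
    """
    config = config or ANNConfig()
    if len(features) < 4:
        raise ValueError("need at least two samples per class")
    lengths = {fv.values.size for fv in features}
    if len(lengths) != 1:
        raise ValueError(f"feature vectors have mixed lengths: {sorted(lengths)}")
    X, y = _as_matrix(features)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValueError(
            f"need >= 2 samples per class, got autistic={counts[0]}, normal={counts[1]}"
        )

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xn = (X - center) / scale
    n, d = Xn.shape
    T = np.zeros((n, 2))
    T[np.arange(n), y] = 1.0

    rng = np.random.default_rng(config.seed)
    W1 = rng.uniform(-0.5, 0.5, (config.hidden, d)) / np.sqrt(d)
    b1 = np.zeros(config.hidden)
    W2 = rng.uniform(-0.5, 0.5, (2, config.hidden)) / np.sqrt(config.hidden)
    b2 = np.zeros(2)
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)

    losses: list[float] = []
    prev = np.inf
    for _ in range(config.epochs):
        H, P = _forward((W1, b1, W2, b2), Xn)
        loss = float(-np.mean(np.log(np.clip(P[np.arange(n), y], 1e-300, None))))
        losses.append(loss)

        G2 = (P - T) / n                      # (n, 2)
        gW2 = G2.T @ H; gb2 = G2.sum(axis=0)
        G1 = (G2 @ W2) * H * (1.0 - H)        # (n, hidden)
        gW1 = G1.T @ Xn; gb1 = G1.sum(axis=0)

        vW2 = config.momentum * vW2 - config.lr * gW2
        vb2 = config.momentum * vb2 - config.lr * gb2
        vW1 = config.momentum * vW1 - config.lr * gW1
        vb1 = config.momentum * vb1 - config.lr * gb1
        W2 += vW2; b2 += vb2; W1 += vW1; b1 += vb1

        if abs(prev - loss) < config.tol:
            break
        prev = loss

    return ANNModel(W1=W1, b1=b1, W2=W2, b2=b2, center=center, scale=scale,
                    config=config, loss_curve=losses)


def predict(model: ANNModel, features: Sequence[FeatureVector]) -> list[tuple[str, tuple[float, float]]]:
    """Class label and (p_autistic, p_normal) per sample; argmax decision."""
    X = np.stack([fv.values for fv in features])
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model input size "
            f"{model.n_features}"
        )
    Xn = (X - model.center) / model.scale
    _, P = _forward((model.W1, model.b1, model.W2, model.b2), Xn)
    return [(CLASS_ORDER[int(np.argmax(p))], (float(p[0]), float(p[1]))) for p in P]


def predict_proba_positive(model: ANNModel, features: Sequence[FeatureVector]) -> np.ndarray:
    """Probability of the positive (autistic) class per sample."""
    return np.array([p[0] for _, p in predict(model, features)])


def save_model(model: ANNModel, path: str | Path) -> None:
    """Serialise a model as versioned JSON."""
    payload = {
        "format_version": _SERIAL_VERSION,
        "config": asdict(model.config),
        "config_digest": model.config.digest(),
        "class_order": list(CLASS_ORDER),
        "W1": model.W1.tolist(), "b1": model.b1.tolist(),
        "W2": model.W2.tolist(), "b2": model.b2.tolist(),
        "center": model.center.tolist(), "scale": model.scale.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ANNModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _SERIAL_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    return ANNModel(
        W1=np.array(payload["W1"]), b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]), b2=np.array(payload["b2"]),
        center=np.array(payload["center"]), scale=np.array(payload["scale"]),
        config=ANNConfig(**payload["config"]),
    )
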