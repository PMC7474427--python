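"""The small CNN that classifies 64x64x3 spectrogram images into two classes.

Architecture (output dimensions per layer):

    input (3,64,64)
    conv 3x3, 8 filters, stride 1, same pad  -> (8,64,64), rectifier
    max-pool 2x2                             -> (8,32,32)
    conv 3x3, 8 filters                      -> (8,32,32), rectifier
    max-pool 2x2                             -> (8,16,16)
    dense 10, rectifier
    dense 2, softmax

Trained with binary cross-entropy and stochastic gradient descent with
momentum (learning rate 1e-4 by default). The rectifier defaults to the
standard ReLU ``max(0, a)``; ``activation="softplus"`` selects the smooth
variant ``ln(1 + e^a)``. Dropout (rate 0.25) sits after each pooling stage and
after the first dense layer, and is disabled at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    SGD,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool2d,
    Network,
    ReLU,
    Softmax,
    Softplus,
)
from .nn.losses import softmax_cross_entropy
from .preprocess import ImageSet

__all__ = ["CNNTrainConfig", "build_cnn", "cnn_loss", "train_cnn", "predict",
           "CLASS_NAMES"]

CLASS_NAMES = ("left", "right")
_EPS = 1e-12


@dataclass(frozen=True)
class CNNTrainConfig:
    """Training hyper-parameters for the CNN.

    learning_rate : SGD step size (default 1e-4).
    momentum : classical momentum; 0 gives plain SGD.
    epochs, batch_size : schedule (config-exposed; no canonical values exist).
    """

    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 32
    dropout: float = 0.25
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.activation not in ("relu", "softplus"):
            raise ValueError("activation must be 'relu' or 'softplus'")


def _rect(activation: str):
    return ReLU() if activation == "relu" else Softplus()


def build_cnn(n_filters: int = 8, dense_units: int = 10, n_classes: int = 2,
              dropout: float = 0.25, activation: str = "relu",
              seed: int = 0) -> Network:
    """Build the two-conv-block CNN; defaults reproduce the reference shapes.

    Overrides that cannot produce a valid network (non-positive sizes) raise.
    """
    if n_filters < 1 or dense_units < 1 or n_classes < 2:
        raise ValueError("n_filters, dense_units must be >= 1 and n_classes >= 2")
    if activation not in ("relu", "softplus"):
        raise ValueError("activation must be 'relu' or 'softplus'")
    rng = np.random.default_rng(seed)
    flat = n_filters * 16 * 16
    return Network([
        Conv2d(3, n_filters, kernel=3, stride=1, pad=1, rng=rng),
        _rect(activation),
        MaxPool2d(2),
        Dropout(dropout),
        Conv2d(n_filters, n_filters, kernel=3, stride=1, pad=1, rng=rng),
        _rect(activation),
        MaxPool2d(2),
        Dropout(dropout),
        Flatten(),
        Dense(flat, dense_units, rng=rng),
        _rect(activation),
        Dropout(dropout),
        Dense(dense_units, n_classes, rng=rng),
        Softmax(),
    ])


def cnn_loss(probabilities, labels) -> float:
    """Mean binary cross-entropy −[y ln ŷ + (1−y) ln(1−ŷ)] on class-1 scores.

    ``probabilities`` is (n, 2) softmax rows (or a 1-D array of class-1
    probabilities); ``labels`` are 0/1 integers. Probabilities are clipped at
    1e-12 so exact 0/1 predictions stay finite.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    p1 = probabilities[:, 1] if probabilities.ndim == 2 else probabilities
    p1 = np.clip(p1, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(p1) + (1.0 - y) * np.log(1.0 - p1)).mean())


def _to_batch(images) -> tuple[np.ndarray, np.ndarray]:
    """ImageSet -> (x in NCHW scaled to [-1,1], integer labels)."""
    if isinstance(images, ImageSet):
        pixels, labels = images.pixels, images.labels
    else:
        pixels, labels = images
    x = np.asarray(pixels, dtype=np.float32).transpose(0, 3, 1, 2) * 2.0 - 1.0
    y = np.array([CLASS_NAMES.index(str(l)) for l in np.asarray(labels)])
    return x, y


def train_cnn(images, config: CNNTrainConfig = CNNTrainConfig(),
              model: Network | None = None) -> tuple[Network, list[float]]:
    """Train the CNN on an ImageSet; returns (model, per-epoch mean loss).

    Deterministic given ``config.seed``. Requires at least one image per
    class — a single-class training set cannot define the decision problem.
    """
    x, y = _to_batch(images)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_cnn(dropout=config.dropout, activation=config.activation,
                          seed=int(rng.integers(2**31)))
    opt = SGD(model.params(), lr=config.learning_rate, momentum=config.momentum)
    n = x.shape[0]
    batch = min(config.batch_size, n)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - batch + 1, batch):
            idx = order[start : start + batch]
            probs = model.forward(x[idx], train=True, rng=rng)
            loss, dprobs = softmax_cross_entropy(probs, y[idx])
            model.zero_grad()
            model.backward(dprobs.astype(probs.dtype))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict(model: Network, images) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class probabilities (dropout off, batch-order free).

    Returns ``(labels, probabilities)`` with labels as class-name strings and
    probability rows summing to one.
    """
    x, _ = _to_batch(images) if isinstance(images, ImageSet) else (
        np.asarray(images, dtype=np.float32).transpose(0, 3, 1, 2) * 2.0 - 1.0,
        None,
    )
    probs = model.forward(x, train=False)
    idx = probs.argmax(axis=1)
    labels = np.array([CLASS_NAMES[i] for i in idx])
    return labels, probs
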