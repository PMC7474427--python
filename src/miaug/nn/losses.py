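"""Loss functions returning (value, gradient-w.r.t.-prediction)."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def binary_cross_entropy(pred, target, *, clip=_EPS):
    """Mean binary cross-entropy −[t·ln p + (1−t)·ln(1−p)] and its gradient.

    ``pred`` and ``target`` are broadcast-compatible arrays of probabilities /
    {0,1} labels. Predictions are clipped away from 0 and 1 before the logs so
    saturated scores stay finite.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    p = np.clip(pred, clip, 1.0 - clip)
    n = p.size
    loss = -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).sum() / n
    grad = (-(target / p) + (1.0 - target) / (1.0 - p)) / n
    return loss, grad


def softmax_cross_entropy(probs, labels, *, clip=_EPS):
    """Mean categorical cross-entropy on softmax outputs and its gradient.

    ``probs`` is (N, K) rows summing to one; ``labels`` integer class ids.
    The gradient is taken w.r.t. the probabilities (backpropagate it through a
    Softmax layer to recover the usual ``p − y`` logit gradient).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    n = probs.shape[0]
    p = np.clip(probs, clip, 1.0)
    loss = -np.log(p[np.arange(n), labels]).sum() / n
    grad = np.zeros_like(p)
    grad[np.arange(n), labels] = -1.0 / (p[np.arange(n), labels] * n)
    return loss, grad
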