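"""Activation functions, the BCE-Dice composite loss, and the metric suite.

Everything here operates on plain :class:`numpy.ndarray` objects and is shared
by the network layers, the training loop, and the evaluation code.

Conventions
-----------
* Ground-truth masks ``y`` are binary arrays (values in {0, 1}).
* Predictions ``p`` are probabilities in [0, 1]; metric functions that need a
  binary prediction take it pre-thresholded.
* The Dice coefficient uses the smoothed form
  ``2 * sum(y * p) / (sum(y) + sum(p) + epsilon)`` so it is defined (and
  differentiable, in its soft form) even for empty masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: smoothing constant of the Dice coefficient denominator
DICE_EPSILON = 1e-5

#: probability clamp applied before taking logs in the cross-entropy
BCE_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def sigmoid(x):
    """Logistic function ``1 / (1 + exp(-x))``, overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def swish(x, beta: float = 1.0):
    """``x * sigmoid(beta * x)``; ``beta=1`` is the fixed (non-trainable) form."""
    x = np.asarray(x, dtype=float)
    return x * sigmoid(beta * x)


def softplus(x):
    """``ln(1 + exp(x))`` computed as ``max(x,0) + log1p(exp(-|x|))``."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def mish(x):
    """``x * tanh(softplus(x))``."""
    x = np.asarray(x, dtype=float)
    return x * np.tanh(softplus(x))


def relu(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def leaky_relu(x, a: float = 0.1):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, a * x)


ACTIVATIONS = {
    "relu": relu,
    "leaky_relu": leaky_relu,
    "swish": swish,
    "mish": mish,
    "sigmoid": sigmoid,
}


@dataclass(frozen=True)
class ActivationKind:
    """Named activation plus the parameters that only some kinds carry."""

    name: str = "swish"
    leaky_slope: float = 0.1
    trainable_beta: bool = False

    def __post_init__(self):
        if self.name not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.name!r}")

    def __call__(self, x):
        if self.name == "leaky_relu":
            return leaky_relu(x, self.leaky_slope)
        return ACTIVATIONS[self.name](x)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossTerms:
    """The two components of the composite loss and their sum."""

    bce: float
    dice_loss: float
    total: float
    epsilon: float = DICE_EPSILON


def _check_shapes(y, p):
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    return y, p


def bce_loss(y, p) -> float:
    """Mean binary cross-entropy with probabilities clamped away from {0, 1}."""
    y, p = _check_shapes(y, p)
    p = np.clip(p, BCE_CLAMP, 1.0 - BCE_CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_coefficient(y, p, epsilon: float = DICE_EPSILON) -> float:
    """Smoothed (soft) Dice overlap; works for probabilities or binary masks."""
    y, p = _check_shapes(y, p)
    inter = float(np.sum(y * p))
    return 2.0 * inter / (float(np.sum(y)) + float(np.sum(p)) + epsilon)


def dice_loss(y, p, epsilon: float = DICE_EPSILON) -> float:
    return 1.0 - dice_coefficient(y, p, epsilon)


def bce_dice_loss(y, p) -> LossTerms:
    """Composite loss: sum of mean BCE and the soft Dice loss."""
    b = bce_loss(y, p)
    d = dice_loss(y, p)
    return LossTerms(bce=b, dice_loss=d, total=b + d)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Pooled pixel-level evaluation record.

    The ratio metrics come from the pooled confusion counts of every pixel in
    the evaluated set ("micro" aggregation); ``loss``/``dice_loss`` are the
    composite loss terms computed on the soft probability maps, while
    ``dice_coefficient``/``jaccard`` are the hard-mask overlaps after
    thresholding.
    """

    accuracy: float
    precision: float
    f1: float
    sensitivity: float
    specificity: float
    dice_coefficient: float
    jaccard: float
    loss: float = float("nan")
    dice_loss: float = float("nan")

    COLUMNS = (
        "accuracy", "loss", "dice_loss", "precision", "f1",
        "sensitivity", "specificity", "dice_coefficient", "jaccard",
    )

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


def _ratio(num: float, den: float) -> float:
    """num/den with the 0/0 convention: 1 if no errors were possible, else 0."""
    if den == 0:
        return 1.0
    return num / den


def confusion_metrics(y, p_bin, loss: float = float("nan"),
                      dice_loss_value: float = float("nan")) -> MetricsReport:
    """Pooled pixel-count metrics between binary truth ``y`` and prediction ``p_bin``."""
    y, p = _check_shapes(y, p_bin)
    if not np.isin(y, (0, 1)).all() or not np.isin(p, (0, 1)).all():
        raise ValueError("confusion_metrics requires strictly binary inputs")
    tp = float(np.sum((y == 1) & (p == 1)))
    fp = float(np.sum((y == 0) & (p == 1)))
    tn = float(np.sum((y == 0) & (p == 0)))
    fn = float(np.sum((y == 1) & (p == 0)))
    total = tp + fp + tn + fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2 * precision * recall, precision + recall) if precision + recall > 0 else 0.0
    if tp + fp == 0 and fn == 0:
        f1 = 1.0
    return MetricsReport(
        accuracy=_ratio(tp + tn, total),
        precision=precision,
        f1=f1,
        sensitivity=recall,
        specificity=_ratio(tn, tn + fp),
        dice_coefficient=dice_coefficient(y, p),
        jaccard=_ratio(tp, tp + fp + fn),
        loss=loss,
        dice_loss=dice_loss_value,
    )
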