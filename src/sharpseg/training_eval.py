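"""Training loop, validation-based model selection, thresholding, evaluation.

Training minimizes the BCE + soft-Dice loss with Adam (learning rate 0.001,
beta1 0.9, beta2 0.9, epsilon 1e-7 — note beta2 is 0.9, not the common
0.999). Augmentation is applied on the fly to training batches only; the
validation set is scored un-augmented after every epoch, the best weights
(by validation soft Dice) are checkpointed, and training stops early after
a patience of non-improving epochs.

The probability-to-mask threshold is derived from the pooled-pixel ROC curve
of the *validation* predictions (Youden's J, max TPR - FPR); when derivation
is skipped the default is 0.4. The test set never influences the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .augmentation import AugmentationConfig, apply_transform, sample_transform
from .enhancement import ClaheConfig, apply_clahe
from .io_dataset import resize_pair
from .nn.layers import Adam
from .nn.ops import bce_dice_from_logits
from .nn_primitives import MetricsReport, confusion_metrics, dice_coefficient

DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.9
    adam_epsilon: float = 1e-7
    early_stop_patience: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    best_epoch: int = -1

    def to_rows(self):
        for e, row in enumerate(zip(self.train_loss, self.train_dice,
                                    self.val_loss, self.val_dice)):
            yield (e,) + row


def preprocess_records(records, side: int, clahe: ClaheConfig = None):
    """Load, optionally CLAHE-enhance, and resize records to ``side``.

    Enhancement happens at native resolution, before resizing. Returns
    ``(images_uint8, masks_uint8)`` stacked as (n, side, side).
    """
    images, masks = [], []
    for rec in records:
        image, mask = rec.load()
        if clahe is not None:
            image = apply_clahe(image, clahe)
        image, mask = resize_pair(image, mask, side)
        images.append(image)
        masks.append(mask)
    return np.stack(images), np.stack(masks)


def _to_float(images: np.ndarray) -> np.ndarray:
    return (images.astype(np.float32) / 255.0)[..., None]


def _soft_dice_on_set(model, images: np.ndarray, masks: np.ndarray,
                      batch_size: int) -> tuple:
    """Pooled soft Dice and mean composite loss over a set, dropout off."""
    probs = model.predict_batched(_to_float(images), batch_size)
    y = masks.astype(np.float32)[..., None]
    d = dice_coefficient(y, probs)
    eps = 1e-7
    p = np.clip(probs, eps, 1 - eps)
    bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return d, bce + (1.0 - d)


def train(model, train_images, train_masks, val_images, val_masks,
          tcfg: TrainingConfig = TrainingConfig(),
          acfg: AugmentationConfig = None,
          verbose: bool = False):
    """Fit ``model`` in place; returns ``(model, TrainingHistory)``.

    ``*_images`` are uint8 stacks, ``*_masks`` binary stacks, all already
    preprocessed to the network input size. The best-validation weights are
    restored into the model before returning.
    """
    if len(train_images) == 0:
        raise ValueError("empty training split")
    # calibrate the output layer to the foreground prior: with a zero head
    # bias the net starts at p=0.5 everywhere and spends its first updates
    # re-learning the class prevalence; starting at the log-odds of the
    # training prevalence removes that transient
    prior = float(np.clip(train_masks.mean(), 1e-4, 1 - 1e-4))
    if hasattr(model, "head") and model.head.b is not None:
        model.head.b.data[:] = np.log(prior / (1.0 - prior))
    rng = np.random.default_rng(tcfg.seed)
    aug_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    opt = Adam(model.parameters(), lr=tcfg.learning_rate, beta1=tcfg.beta1,
               beta2=tcfg.beta2, eps=tcfg.adam_epsilon)
    history = TrainingHistory()
    best_dice, best_weights, since_best = -np.inf, None, 0
    n = len(train_images)

    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_dice, n_batches = 0.0, 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            batch_i, batch_m = [], []
            for k in idx:
                img, msk = train_images[k], train_masks[k]
                if acfg is not None:
                    params = sample_transform(acfg, aug_rng)
                    img, msk = apply_transform(img, msk, params)
                batch_i.append(img)
                batch_m.append(msk)
            xb = _to_float(np.stack(batch_i))
            yb = np.stack(batch_m).astype(np.float32)[..., None]
            opt.zero_grad()
            logits = model.forward(xb, training=True, rng=drop_rng)
            loss, _, dloss = bce_dice_from_logits(logits, yb)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            epoch_dice += 1.0 - dloss
            n_batches += 1
        val_dice, val_loss = _soft_dice_on_set(model, val_images, val_masks,
                                               tcfg.batch_size)
        history.train_loss.append(epoch_loss / n_batches)
        history.train_dice.append(epoch_dice / n_batches)
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        if verbose:
            print(f"epoch {epoch:3d}  train loss {history.train_loss[-1]:.4f}"
                  f"  val dice {val_dice:.4f}")
        if val_dice > best_dice:
            best_dice, best_weights = val_dice, model.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.early_stop_patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history


def derive_threshold(probs, truths) -> float:
    """Youden-optimal threshold of the pooled-pixel ROC curve."""
    y = np.asarray(truths).ravel()
    p = np.asarray(probs).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("threshold derivation needs both classes present")
    fpr, tpr, thresholds = roc_curve(y, p)
    j = tpr - fpr
    t = float(thresholds[np.argmax(j)])
    # roc_curve's first threshold exceeds every score; clamp into (0, 1)
    return min(max(t, np.nextafter(0.0, 1.0)), 1.0 - 1e-12)


def binarize(probs, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Pixel = 1 iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    return (np.asarray(probs) >= threshold).astype(np.uint8)


def evaluate(model, images: np.ndarray, masks: np.ndarray,
             threshold: float = DEFAULT_THRESHOLD,
             batch_size: int = 16) -> MetricsReport:
    """Inference + thresholding + pooled metrics on a preprocessed test set."""
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    probs = model.predict_batched(_to_float(images), batch_size)
    y = masks.astype(np.float32)[..., None]
    soft_dice, loss = _soft_dice_on_set(model, images, masks, batch_size)
    pred = binarize(probs, threshold)
    return confusion_metrics(y, pred, loss=loss,
                             dice_loss_value=1.0 - soft_dice)


def predict_masks(model, images: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD,
                  batch_size: int = 16) -> np.ndarray:
    """Binary predicted masks ``(n, side, side)`` for a preprocessed stack."""
    probs = model.predict_batched(_to_float(images), batch_size)
    return binarize(probs, threshold)[..., 0]
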