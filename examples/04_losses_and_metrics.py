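"""The BCE-Dice composite loss and the pooled evaluation metric suite."""

import numpy as np

from sharpseg import bce_dice_loss, confusion_metrics, dice_coefficient, swish, mish

# activations used by the networks
print("swish(1) =", round(float(swish(1.0)), 6), " mish(1) =",
      round(float(mish(1.0)), 6))

# composite loss on a toy prediction: one foreground pixel predicted at 0.5
terms = bce_dice_loss(np.array([1.0]), np.array([0.5]))
print(f"bce = {terms.bce:.4f} (ln 2), dice loss = {terms.dice_loss:.4f}, "
      f"total = {terms.total:.4f}")

# pooled pixel metrics on a synthetic confusion pattern:
# 3 true positives, 1 false positive, 1 false negative, 95 true negatives
y = np.array([1] * 4 + [0] * 96, dtype=float)
p = np.array([1] * 3 + [0] + [1] + [0] * 95, dtype=float)
report = confusion_metrics(y, p)
print("precision", report.precision, "sensitivity", report.sensitivity,
      "f1", round(report.f1, 4), "jaccard", report.jaccard)
print("dice", round(report.dice_coefficient, 4),
      "= 2J/(1+J):", round(2 * report.jaccard / (1 + report.jaccard), 4))
# Dice and Jaccard are linked by D = 2J/(1+J); both come from the same
# pooled pixel counts.
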