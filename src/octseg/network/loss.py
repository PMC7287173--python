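"""Soft-Dice loss.

The loss is one minus twice the soft overlap between the predicted class
probabilities p_l(x) and the one-hot ground truth g_l(x), with sums taken
jointly over all pixels and classes (a single global ratio):

    loss = 1 - 2 * sum(p*g) / (sum(p^2) + sum(g^2))

It is 0 exactly when the prediction is the hard one-hot ground truth and 1
when the supports are disjoint; training minimizes it.  A per-class-averaged
variant is available via ``mode="per_class"``.
"""

from __future__ import annotations

import numpy as np

_EPS_DOC = "both maps identically zero -> vacuous perfect match, loss 0"


def soft_dice_loss(pred: np.ndarray, gt_onehot: np.ndarray,
                   mode: str = "global") -> float:
    """Soft-Dice loss between probabilities and one-hot ground truth.

    Both arrays share a shape whose first (or second, if batched) axis is the
    class axis; any layout works since the global mode sums everything.
    """
    if pred.shape != gt_onehot.shape:
        raise ValueError("pred and gt shapes differ")
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt_onehot, dtype=np.float64)
    if mode == "global":
        num = 2.0 * (p * g).sum()
        den = (p * p).sum() + (g * g).sum()
        return 0.0 if den == 0.0 else float(1.0 - num / den)
    if mode == "per_class":
        # class axis: first axis for (C,H,W), second for (B,C,H,W)
        caxis = 0 if p.ndim == 3 else 1
        p2 = np.moveaxis(p, caxis, 0).reshape(p.shape[caxis], -1)
        g2 = np.moveaxis(g, caxis, 0).reshape(p.shape[caxis], -1)
        num = 2.0 * (p2 * g2).sum(axis=1)
        den = (p2 * p2).sum(axis=1) + (g2 * g2).sum(axis=1)
        dice = np.where(den == 0.0, 1.0, num / np.where(den == 0.0, 1.0, den))
        return float(1.0 - dice.mean())
    raise ValueError(f"unknown mode {mode!r}")


def soft_dice_grad(pred: np.ndarray, gt_onehot: np.ndarray) -> np.ndarray:
    """Gradient of the global Soft-Dice loss w.r.t. the probabilities.

    With A = sum(p*g), B = sum(p^2)+sum(g^2):
    d(1 - 2A/B)/dp = -2g/B + 4A p / B^2.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt_onehot, dtype=np.float64)
    A = (p * g).sum()
    B = (p * p).sum() + (g * g).sum()
    if B == 0.0:
        return np.zeros_like(p)
    return -2.0 * g / B + 4.0 * A * p / (B * B)
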