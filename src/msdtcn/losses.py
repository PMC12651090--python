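"""Segmentation objectives: pixel BCE, soft Dice, and their weighted hybrid.

All losses operate on foreground *probabilities* (post-sigmoid) and binary
targets; they accept autograd tensors (for training) or plain arrays and
always return a scalar :class:`~msdtcn.nn.Tensor`.
"""

from __future__ import annotations

from .nn.tensor import Tensor, astensor, clip, log

__all__ = ["bce_loss", "dice_loss", "hybrid_loss", "CLAMP"]

#: probability clamp applied before logarithms
CLAMP = 1e-7


def bce_loss(probs, target) -> Tensor:
    """Mean binary cross-entropy over all pixels."""
    p, t = astensor(probs), astensor(target)
    if p.shape != t.shape:
        raise ValueError("probs and target shapes differ")
    p = clip(p, CLAMP, 1.0 - CLAMP)
    return -(t * log(p) + (1.0 - t) * log(1.0 - p)).mean()


def dice_loss(probs, target, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)."""
    p, t = astensor(probs), astensor(target)
    if p.shape != t.shape:
        raise ValueError("probs and target shapes differ")
    if eps <= 0:
        raise ValueError("eps must be positive")
    inter = (p * t).sum()
    return 1.0 - (2.0 * inter + eps) / (p.sum() + t.sum() + eps)


def hybrid_loss(probs, target, bce_weight: float = 0.6,
                dice_weight: float = 0.4, eps: float = 1e-6) -> Tensor:
    """Weighted combination 0.6 * BCE + 0.4 * Dice (defaults)."""
    return (bce_weight * bce_loss(probs, target)
            + dice_weight * dice_loss(probs, target, eps))
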