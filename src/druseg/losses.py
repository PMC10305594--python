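"""Segmentation losses: Dice (squared-denominator form), voxel-averaged
binary cross-entropy, and their average (the DBCE hybrid).

All losses take a predicted probability grid ``p`` in [0, 1] and a binary
ground-truth grid ``g`` of the same shape, and return a non-negative scalar.
Each also exposes the analytic gradient with respect to ``p`` (``with_grad=
True``), which is what the training loop backpropagates; the gradients are
verified against finite differences in the test suite.

The Dice loss uses the squared-denominator form

    L_dice = 1 - 2 * sum(p * g) / (sum(p**2) + sum(g**2) + eps)

which for binary ``p`` collapses to ``1 - DSC``.  When both ``p`` and ``g``
are identically zero the ratio is 0/eps; we define that case as loss 0
(perfect agreement on emptiness) rather than 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice_loss", "bce_loss", "dbce_loss", "loss_and_grad", "LOSSES"]

_EPS = 1e-6
_CLAMP = 1e-7


def _validate(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs g {g.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    bad = np.setdiff1d(np.unique(g), [0.0, 1.0])
    if bad.size:
        raise ValueError(f"ground truth must be binary; found values {bad}")
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValueError("predictions must lie in [0, 1]")
    return p, g


def dice_loss(p, g, eps: float = _EPS, with_grad: bool = False):
    """Soft Dice loss with squared denominator."""
    p, g = _validate(p, g)
    inter = float((p * g).sum())
    denom = float((p * p).sum() + (g * g).sum())
    if denom == 0.0:
        # both grids identically zero: treat as perfect agreement
        loss = 0.0
        if with_grad:
            return loss, np.zeros_like(p)
        return loss
    b = denom + eps
    loss = 1.0 - 2.0 * inter / b
    if with_grad:
        grad = (-2.0 * g * b + 4.0 * inter * p) / (b * b)
        return loss, grad
    return loss


def bce_loss(p, g, clamp: float = _CLAMP, with_grad: bool = False):
    """Binary cross-entropy, averaged over voxels, with probability clamping
    to [clamp, 1-clamp] before the logarithms."""
    p, g = _validate(p, g)
    pc = np.clip(p, clamp, 1.0 - clamp)
    n = p.size
    loss = float(-(g * np.log(pc) + (1.0 - g) * np.log1p(-pc)).mean())
    if with_grad:
        grad = (-(g / pc) + (1.0 - g) / (1.0 - pc)) / n
        # clamped voxels sit on a flat region of the surrogate
        grad[(p < clamp) | (p > 1.0 - clamp)] = 0.0
        return loss, grad
    return loss


def dbce_loss(p, g, eps: float = _EPS, clamp: float = _CLAMP,
              with_grad: bool = False):
    """Hybrid loss: arithmetic mean of BCE and Dice losses."""
    if with_grad:
        ld, gd = dice_loss(p, g, eps, with_grad=True)
        lb, gb = bce_loss(p, g, clamp, with_grad=True)
        return 0.5 * (lb + ld), 0.5 * (gb + gd)
    return 0.5 * (bce_loss(p, g, clamp) + dice_loss(p, g, eps))


LOSSES = {"dice": dice_loss, "bce": bce_loss, "dbce": dbce_loss}


def loss_and_grad(name: str, p, g):
    """Evaluate a loss by name, returning ``(value, d(value)/dp)``."""
    try:
        fn = LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(LOSSES)}")
    return fn(p, g, with_grad=True)
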