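"""Negative soft-Dice loss with optional voxel masking."""

from __future__ import annotations

import numpy as np

__all__ = ["dice_loss_and_grad", "soft_dice"]

_EPS = 1e-6


def soft_dice(pred, target, mask=None, eps=_EPS):
    """Per-channel soft Dice of channels-last arrays (B, *S, C)."""
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if mask is not None:
        mask = np.asarray(mask, dtype=np.float32)
        pred = pred * mask
        target = target * mask
    axes = tuple(range(pred.ndim - 1))
    num = 2.0 * (pred * target).sum(axis=axes) + eps
    den = pred.sum(axis=axes) + target.sum(axis=axes) + eps
    return num / den


def dice_loss_and_grad(pred, target, mask=None, eps=_EPS):
    """Negative soft Dice averaged over channels, and d(loss)/d(pred).

    A prediction identical to the target scores -1. With ``mask`` the
    sums run only over voxels where mask is nonzero; the gradient is
    exactly zero elsewhere.
    """
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    m = None
    if mask is not None:
        m = np.asarray(mask, dtype=np.float32)
        pred_m = pred * m
        target_m = target * m
    else:
        pred_m, target_m = pred, target
    axes = tuple(range(pred.ndim - 1))
    num = 2.0 * (pred_m * target_m).sum(axis=axes) + eps
    den = pred_m.sum(axis=axes) + target_m.sum(axis=axes) + eps
    loss = -float(np.mean(num / den))
    # d/dp of -(num/den): -(2*t*den - num) / den^2, averaged over channels
    n_ch = pred.shape[-1]
    grad = -(2.0 * target_m * den - num) / (den**2) / n_ch
    if m is not None:
        grad = grad * m
    return loss, grad.astype(np.float32)
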