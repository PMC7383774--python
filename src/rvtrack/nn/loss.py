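"""Class-weighted softmax cross-entropy.

Per pixel with logit vector x and true class i the loss is
``-W[i] * ln(softmax(x)[i])``; the scalar loss is the plain mean of the
weighted per-pixel terms over every pixel in the batch (not renormalized
by the weight mass — this choice sets the numeric scale of reported
losses and is applied consistently in training and evaluation). Class
weighting counteracts the extreme background/annulus pixel imbalance;
the annular classes carry weight 0.8 against 0.2 for background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LossConfig:
    """Per-class weights W (background first)."""

    class_weights: tuple[float, ...] = (0.2, 0.8, 0.8)

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if (w < 0).any():
            raise ValueError("class weights must be nonnegative")
        if not (w > 0).any():
            raise ValueError("at least one class weight must be positive")


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_ce_loss(
    logits: np.ndarray,
    truth: np.ndarray,
    weights: LossConfig | np.ndarray,
    return_grad: bool = False,
):
    """Mean weighted cross-entropy over a batch of pixel logits.

    Parameters
    ----------
    logits
        ``(N, C, H, W)`` (or ``(N, C)`` for bare pixel batches).
    truth
        Integer class labels, ``(N, H, W)`` (or ``(N,)``).
    weights
        ``LossConfig`` or a length-C nonnegative vector.
    return_grad
        Also return d(loss)/d(logits), same shape as ``logits``.
    """
    w = np.asarray(weights.class_weights if isinstance(weights, LossConfig)
                   else weights, dtype=np.float64)
    logits = np.asarray(logits)
    truth = np.asarray(truth)
    if logits.ndim == 2:
        logits = logits[:, :, None, None]
        truth = truth[:, None, None]
    n, c, h, wd = logits.shape
    if w.shape != (c,):
        raise ValueError(f"need {c} class weights, got {w.shape}")
    if truth.min() < 0 or truth.max() >= c:
        raise ValueError(f"truth labels outside [0, {c})")

    p = softmax(logits.astype(np.float64), axis=1)
    pix_w = w[truth]  # (N, H, W)
    idx = np.ogrid[:n, :h, :wd]
    p_true = p[idx[0], truth, idx[1], idx[2]]
    npix = n * h * wd
    loss = float((-pix_w * np.log(np.maximum(p_true, 1e-30))).sum() / npix)
    if not return_grad:
        return loss
    onehot = np.zeros_like(p)
    onehot[idx[0], truth, idx[1], idx[2]] = 1.0
    grad = (p - onehot) * pix_w[:, None, :, :] / npix
    return loss, grad.astype(logits.dtype, copy=False)
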