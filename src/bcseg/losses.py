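"""Smoothed Dice loss for training and the Dice overlap score for evaluation.

The training loss is the soft Dice complement

    loss = 1 - (2 * sum(p * g) + smooth) / (sum(p) + sum(g) + smooth)

with smooth = 1 by default; the smoothing term keeps the ratio finite when
prediction and reference are both empty and stabilizes near-empty targets.
For a binarized prediction the soft form reduces to the set form
1 - (2|A∩B| + smooth) / (|A| + |B| + smooth) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ndnn.autograd import Tensor
from .types import BinaryMask


@dataclass(frozen=True)
class DiceParams:
    smooth: float = 1.0

    def __post_init__(self):
        if self.smooth <= 0:
            raise ValueError(f"smooth must be positive, got {self.smooth}")


def _mask_array(m) -> np.ndarray:
    return m.pixels if isinstance(m, BinaryMask) else np.asarray(m)


def dice_loss(pred, target, params: DiceParams = DiceParams()):
    """Soft Dice loss between a probability map and a binary reference.

    ``pred`` may be an ndarray (returns a float) or an ``ndnn`` Tensor with
    leading batch/channel axes (returns a scalar Tensor, averaged per image
    over the batch, so the gradient matches per-image-loss training).
    """
    if isinstance(pred, Tensor):
        return _dice_loss_tensor(pred, target, params)
    p = np.asarray(pred, dtype=np.float64)
    g = _mask_array(target).astype(np.float64)
    if p.shape != g.shape:
        raise ValueError(f"dice_loss: shape mismatch {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("dice_loss: pred must lie in [0, 1]")
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum())
    return 1.0 - (2.0 * inter + params.smooth) / (denom + params.smooth)


def _dice_loss_tensor(pred: Tensor, target, params: DiceParams) -> Tensor:
    """Per-image soft Dice loss averaged over the batch, as one custom op.

    The gradient of loss_i = 1 - (2 I_i + s)/(D_i + s) w.r.t. p is
    -(2 g (D_i + s) - (2 I_i + s)) / (D_i + s)^2, applied with the 1/n batch
    averaging folded in.
    """
    g = np.asarray(target, dtype=pred.data.dtype)
    if g.shape != pred.data.shape:
        raise ValueError(f"dice_loss: shape mismatch {pred.data.shape} vs {g.shape}")
    n = pred.data.shape[0]
    axes = tuple(range(1, pred.data.ndim))
    s = params.smooth
    inter = (pred.data * g).sum(axis=axes)
    denom = pred.data.sum(axis=axes) + g.sum(axis=axes) + s
    losses = 1.0 - (2.0 * inter + s) / denom
    out_data = np.asarray(losses.mean(), dtype=pred.data.dtype)

    def backward(gout):
        shape = (n,) + (1,) * (pred.data.ndim - 1)
        dden = denom.reshape(shape)
        dnum = (2.0 * inter + s).reshape(shape)
        grad = -(2.0 * g * dden - dnum) / (dden ** 2)
        pred._accumulate(gout * grad / n)

    req = pred.requires_grad
    return Tensor(out_data, requires_grad=req, _parents=(pred,) if req else (),
                  _backward=backward if req else None)


def dice_score(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on absence).
    """
    pa = _mask_array(a).astype(bool)
    pb = _mask_array(b).astype(bool)
    if pa.shape != pb.shape:
        raise ValueError(f"dice_score: shape mismatch {pa.shape} vs {pb.shape}")
    denom = int(pa.sum()) + int(pb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / denom
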