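"""Compound multi-task objective.

L_total = L_seg + L_cls, with unit task weights, where
L_seg = L_CE + L_Dice:

* L_CE   — voxel-wise cross-entropy, mean over all voxels of
           -sum_c y_{i,c} log p_{i,c} (C = 2: background, nodule);
* L_Dice — soft Dice loss on the nodule channel,
           1 - (2 sum_i p_{i,1} y_{i,1} + eps) / (sum_i p_{i,1} + sum_i y_{i,1} + eps),
           eps = 1e-5 for numerical stability;
* L_cls  — batch-mean cross-entropy on the 2-class malignancy prediction.

All three accept probabilities (post-softmax), as numpy arrays or autograd
tensors; when given tensors the returned scalars carry gradients, so the
same code path serves evaluation and training. CE terms floor the
probability at 1e-12 before the log (the losses are undefined at p = 0).

Per-sample convention: CE and Dice are computed per sample then averaged
over the batch, matching the per-case evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .nn import Tensor, as_tensor

EPS_DICE = 1e-5
LOG_FLOOR = 1e-12

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass(frozen=True)
class LossBreakdown:
    """Total loss and its components for one batch (plain floats)."""

    l_total: float
    l_seg: float
    l_ce: float
    l_dice: float
    l_cls: float

    def as_dict(self) -> dict:
        return {
            "l_total": self.l_total, "l_seg": self.l_seg,
            "l_ce": self.l_ce, "l_dice": self.l_dice, "l_cls": self.l_cls,
        }


def _check_seg_inputs(seg_probs: Tensor, gt: np.ndarray) -> None:
    if seg_probs.ndim != 5 or seg_probs.shape[1] != 2:
        raise ValueError(f"seg_probs must be (B, 2, D, H, W), got {seg_probs.shape}")
    if gt.shape != (seg_probs.shape[0],) + seg_probs.shape[2:]:
        raise ValueError(f"gt shape {gt.shape} does not match seg_probs {seg_probs.shape}")


def ce_seg_loss(seg_probs: ArrayOrTensor, gt: np.ndarray) -> Tensor:
    """Voxel-wise cross-entropy: mean over voxels of -log p(true class)."""
    seg_probs = as_tensor(seg_probs)
    gt = np.asarray(gt)
    _check_seg_inputs(seg_probs, gt)
    B = seg_probs.shape[0]
    onehot = np.stack([(gt == 0), (gt == 1)], axis=1).astype(seg_probs.data.dtype)
    logp = seg_probs.clip(LOG_FLOOR, 1.0).log()
    per_sample = -(logp * Tensor(onehot)).reshape(B, -1).sum(axis=1) / float(gt[0].size)
    return per_sample.mean()


def dice_loss(seg_probs: ArrayOrTensor, gt: np.ndarray, eps: float = EPS_DICE) -> Tensor:
    """Soft Dice loss on the foreground (nodule) channel, per sample."""
    seg_probs = as_tensor(seg_probs)
    gt = np.asarray(gt)
    _check_seg_inputs(seg_probs, gt)
    B = seg_probs.shape[0]
    p_fg = seg_probs.reshape(B, 2, -1)
    # foreground channel: slice via elementwise select to keep the graph simple
    sel = np.zeros((1, 2, 1), dtype=seg_probs.data.dtype)
    sel[0, 1, 0] = 1.0
    p1 = (p_fg * Tensor(sel)).sum(axis=1)          # (B, N)
    y1 = gt.reshape(B, -1).astype(seg_probs.data.dtype)
    inter = (p1 * Tensor(y1)).sum(axis=1)
    denom = p1.sum(axis=1) + Tensor(y1.sum(axis=1))
    dice = (2.0 * inter + eps) / (denom + eps)
    return (1.0 - dice).mean()


def cls_loss(cls_probs: ArrayOrTensor, labels: Sequence[int]) -> Tensor:
    """Batch-mean cross-entropy of the 2-class malignancy probabilities."""
    cls_probs = as_tensor(cls_probs)
    labels = np.asarray(labels)
    if cls_probs.ndim != 2 or cls_probs.shape[1] != 2:
        raise ValueError(f"cls_probs must be (B, 2), got {cls_probs.shape}")
    if labels.shape != (cls_probs.shape[0],):
        raise ValueError("labels must have one entry per sample")
    onehot = np.stack([(labels == 0), (labels == 1)], axis=1).astype(cls_probs.data.dtype)
    logp = cls_probs.clip(LOG_FLOOR, 1.0).log()
    return -(logp * Tensor(onehot)).sum(axis=1).mean()


def total_loss(
    seg_probs: ArrayOrTensor,
    gt: np.ndarray,
    cls_probs: ArrayOrTensor,
    labels: Sequence[int],
) -> tuple[Tensor, LossBreakdown]:
    """Compound objective; returns the differentiable total and the breakdown."""
    ce = ce_seg_loss(seg_probs, gt)
    dc = dice_loss(seg_probs, gt)
    cl = cls_loss(cls_probs, labels)
    total = ce + dc + cl
    bd = LossBreakdown(
        l_total=total.item(),
        l_seg=ce.item() + dc.item(),
        l_ce=ce.item(),
        l_dice=dc.item(),
        l_cls=cl.item(),
    )
    return total, bd
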