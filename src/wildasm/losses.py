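"""Detection losses: CIoU box regression, distribution focal loss (DFL),
and binary cross-entropy classification with task-aligned soft targets.

``total_loss`` glues them together: raw per-stride logits are flattened to
one anchor list, decoded differentiably (box side = expectation of the
reg_max-bin distribution), assigned to ground truths by the task-aligned
rule, and reduced as

    gain_box * CIoU + gain_cls * BCE + gain_dfl * DFL,

each normalized by the total soft-target mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .assign import task_aligned_assign
from .autograd import Tensor, bce_with_logits, concat, softmax
from .model import Detector

__all__ = ["ciou_loss", "dfl_loss", "bce_cls_loss", "total_loss",
           "flatten_predictions", "LossGains"]

_EPS = 1e-9


@dataclass
class LossGains:
    box: float = 7.5
    cls: float = 0.5
    dfl: float = 1.5


def ciou_loss(pred_boxes, gt_boxes) -> Tensor:
    """1 - CIoU per row; boxes are xyxy with positive area.

    CIoU = IoU - rho^2/c^2 - alpha*v: plain overlap minus a normalized
    center-distance penalty minus an aspect-consistency penalty
    (v = 4/pi^2 * (arctan(w_t/h_t) - arctan(w_p/h_p))^2, with the standard
    trade-off weight alpha = v / (1 - IoU + v) treated as a constant).
    """
    p = pred_boxes if isinstance(pred_boxes, Tensor) else Tensor(pred_boxes)
    t = np.asarray(gt_boxes if not isinstance(gt_boxes, Tensor) else gt_boxes.data,
                   dtype=np.float64)
    t = t.reshape(-1, 4)
    if np.any((t[:, 2] - t[:, 0]) <= 0) or np.any((t[:, 3] - t[:, 1]) <= 0):
        raise ValueError("ground-truth boxes must have positive area")
    px1, py1, px2, py2 = (p[:, i] for i in range(4))
    tx1, ty1, tx2, ty2 = (Tensor(t[:, i]) for i in range(4))
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).maximum(0.0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).maximum(0.0)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter + _EPS
    iou_t = inter / union
    # squared center distance over squared enclosing-box diagonal
    rho2 = ((px1 + px2 - tx1 - tx2) * 0.5) ** 2.0 + ((py1 + py2 - ty1 - ty2) * 0.5) ** 2.0
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw ** 2.0 + ch ** 2.0 + _EPS
    atan_t = ((tx2 - tx1) / (ty2 - ty1 + _EPS)).arctan()
    atan_p = ((px2 - px1) / (py2 - py1 + _EPS)).arctan()
    v = (4.0 / np.pi ** 2) * (atan_t - atan_p) ** 2.0
    alpha = Tensor(v.data / (1.0 - iou_t.data + v.data + _EPS))  # constant weight
    ciou = iou_t - rho2 / c2 - alpha * v
    return 1.0 - ciou


def dfl_loss(bin_logits, target_offset) -> Tensor:
    """Per-anchor distribution focal loss, mean over the four sides.

    Cross-entropy against the two integer bins bracketing the continuous
    target, weighted by linear interpolation; targets outside
    [0, reg_max - 1] are clamped (with a warning).
    """
    logits = bin_logits if isinstance(bin_logits, Tensor) else Tensor(bin_logits)
    n, sides, reg_max = logits.shape
    t = np.asarray(target_offset, dtype=np.float64).reshape(n, sides)
    hi = reg_max - 1 - 1e-3
    if (t < 0).any() or (t > reg_max - 1).any():
        warnings.warn("DFL target offsets outside [0, reg_max-1] were clamped")
    t = t.clip(0.0, hi)
    tl = np.floor(t).astype(int)
    tr = tl + 1
    wl = (tr - t).astype(np.float32)
    wr = 1.0 - wl
    # stable log-softmax: x - max - log(sum exp(x - max))
    m = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - m
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    rows = np.arange(n)[:, None]
    cols = np.arange(sides)[None, :]
    ce_l = (lse[:, :, 0] - z[rows, cols, tl])
    ce_r = (lse[:, :, 0] - z[rows, cols, np.minimum(tr, reg_max - 1)])
    per_side = ce_l * wl + ce_r * wr
    return per_side.mean(axis=1)


def bce_cls_loss(class_logits, target_scores) -> Tensor:
    """Sum of element-wise BCE divided by the total soft-target mass."""
    logits = class_logits if isinstance(class_logits, Tensor) else Tensor(class_logits)
    t = np.asarray(target_scores, dtype=np.float32)
    norm = max(float(t.sum()), 1.0)
    return bce_with_logits(logits, t).sum() * (1.0 / norm)


def flatten_predictions(raw: dict, reg_max: int):
    """Raw per-stride logits -> flattened anchor-major tensors.

    Returns (pred_dist (B, A, 4, reg_max), pred_cls (B, A, nc),
    anchor_points (A, 2) pixel centers, stride_per_anchor (A,)).
    """
    dists, clss, anchors, strides = [], [], [], []
    for stride, (box_t, cls_t) in raw.items():
        b, c4r, h, w = box_t.shape
        d = box_t.reshape(b, 4, reg_max, h, w).transpose(0, 3, 4, 1, 2)
        dists.append(d.reshape(b, h * w, 4, reg_max))
        nc = cls_t.shape[1]
        clss.append(cls_t.transpose(0, 2, 3, 1).reshape(b, h * w, nc))
        ys, xs = np.mgrid[0:h, 0:w]
        anchors.append(np.stack([(xs.ravel() + 0.5) * stride,
                                 (ys.ravel() + 0.5) * stride], axis=1))
        strides.append(np.full(h * w, stride, dtype=np.float32))
    return (concat(dists, axis=1), concat(clss, axis=1),
            np.concatenate(anchors), np.concatenate(strides))


def _decode_boxes(pred_dist: Tensor, anchors: np.ndarray,
                  strides: np.ndarray) -> Tensor:
    """Differentiable decode: expected ltrb distances -> xyxy pixels."""
    reg_max = pred_dist.shape[-1]
    bins = np.arange(reg_max, dtype=np.float32)
    exp = (softmax(pred_dist, axis=-1) * Tensor(bins)).sum(axis=-1)  # (B, A, 4)
    s = strides[None, :, None]
    ltrb = exp * Tensor(np.broadcast_to(s, (1, len(strides), 1)).copy())
    ax = anchors[None, :, 0]
    ay = anchors[None, :, 1]
    x1 = Tensor(ax) - ltrb[:, :, 0]
    y1 = Tensor(ay) - ltrb[:, :, 1]
    x2 = Tensor(ax) + ltrb[:, :, 2]
    y2 = Tensor(ay) + ltrb[:, :, 3]
    from .autograd import stack
    return stack([x1, y1, x2, y2], axis=2)


def total_loss(raw: dict, targets, model: Detector,
               gains: LossGains | None = None,
               assigner_kwargs: dict | None = None):
    """Full detection loss for one batch.

    ``targets``: per image, a (gt_cls (M,), gt_boxes (M, 4) xyxy pixels)
    pair.  Returns (scalar Tensor, components dict with float box/cls/dfl).
    """
    gains = gains or LossGains()
    akw = assigner_kwargs or {}
    reg_max = model.cfg.reg_max
    pred_dist, pred_cls, anchors, strides = flatten_predictions(raw, reg_max)
    pred_boxes = _decode_boxes(pred_dist, anchors, strides)
    B, A, nc = pred_cls.shape

    cls_probs = 0.5 * (1.0 + np.tanh(0.5 * pred_cls.data))
    target_scores = np.zeros((B, A, nc), dtype=np.float32)
    fg_b, fg_a, fg_boxes, fg_weights, fg_ltrb = [], [], [], [], []
    for b, (gt_cls, gt_boxes) in enumerate(targets):
        res = task_aligned_assign(cls_probs[b], pred_boxes.data[b],
                                  np.asarray(gt_boxes, float).reshape(-1, 4),
                                  gt_cls, anchors, **akw)
        target_scores[b] = res.target_scores
        fg = np.flatnonzero(res.fg_mask)
        if len(fg) == 0:
            continue
        fg_b.append(np.full(len(fg), b))
        fg_a.append(fg)
        tb = res.target_boxes[fg]
        fg_boxes.append(tb)
        fg_weights.append(res.target_scores[fg].sum(axis=1))
        # ltrb targets in units of each anchor's grid cell
        ap = anchors[fg]
        st = strides[fg][:, None]
        fg_ltrb.append(np.stack([ap[:, 0] - tb[:, 0], ap[:, 1] - tb[:, 1],
                                 tb[:, 2] - ap[:, 0], tb[:, 3] - ap[:, 1]],
                                axis=1) / st)
    ts_sum = max(float(target_scores.sum()), 1.0)
    cls_component = bce_with_logits(pred_cls, target_scores).sum() * (1.0 / ts_sum)

    if fg_b:
        bi = np.concatenate(fg_b)
        ai = np.concatenate(fg_a)
        w = Tensor(np.concatenate(fg_weights).astype(np.float32))
        boxes_fg = pred_boxes[bi, ai]
        box_component = (ciou_loss(boxes_fg, np.concatenate(fg_boxes)) * w).sum() * (1.0 / ts_sum)
        ltrb_t = np.concatenate(fg_ltrb)
        dist_fg = pred_dist[bi, ai]
        dfl_component = (dfl_loss(dist_fg, ltrb_t) * w).sum() * (1.0 / ts_sum)
    else:
        box_component = Tensor(0.0)
        dfl_component = Tensor(0.0)

    total = (gains.box * box_component + gains.cls * cls_component
             + gains.dfl * dfl_component)
    components = {"box": float(box_component.data),
                  "cls": float(cls_component.data),
                  "dfl": float(dfl_component.data)}
    return total, components
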