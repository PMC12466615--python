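"""Task-aligned label assignment for anchor-free dense prediction.

Each ground-truth box selects its top-k grid points by the alignment metric

    t = s^alpha * u^beta

where s is the predicted probability of the box's class at that point and
u the IoU between the point's decoded box and the ground truth.  Candidates
are restricted to points whose cell center lies inside the box; a point
claimed by several boxes goes to the one it overlaps most.  The soft
classification target of an assigned point is its alignment metric rescaled
so each box's best point carries that box's best IoU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AssignResult", "task_aligned_assign"]


@dataclass
class AssignResult:
    fg_mask: np.ndarray       # (A,) bool
    gt_idx: np.ndarray        # (A,) int, valid where fg_mask
    target_scores: np.ndarray  # (A, nc) soft classification targets
    target_boxes: np.ndarray  # (A, 4) xyxy, valid where fg_mask

    @property
    def n_foreground(self) -> int:
        return int(self.fg_mask.sum())


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = iw * ih
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    return inter / np.maximum(area_a + area_b - inter, 1e-9)


def task_aligned_assign(cls_scores: np.ndarray, pred_boxes: np.ndarray,
                        gt_boxes: np.ndarray, gt_cls: np.ndarray,
                        anchor_points: np.ndarray, topk: int = 10,
                        alpha: float = 0.5, beta: float = 6.0) -> AssignResult:
    """Assign ground truths to anchor points for one image.

    ``cls_scores``: (A, nc) predicted class probabilities (post-sigmoid);
    ``pred_boxes``/``gt_boxes``: xyxy pixels; ``anchor_points``: (A, 2) cell
    centers in pixels.  An image with zero ground truths yields an
    all-background result.
    """
    A, nc = cls_scores.shape
    M = len(gt_boxes)
    if M == 0:
        return AssignResult(np.zeros(A, bool), np.zeros(A, int),
                            np.zeros((A, nc)), np.zeros((A, 4)))
    gt_boxes = np.asarray(gt_boxes, float).reshape(M, 4)
    gt_cls = np.asarray(gt_cls, int)

    inside = ((anchor_points[:, None, 0] > gt_boxes[None, :, 0]) &
              (anchor_points[:, None, 0] < gt_boxes[None, :, 2]) &
              (anchor_points[:, None, 1] > gt_boxes[None, :, 1]) &
              (anchor_points[:, None, 1] < gt_boxes[None, :, 3]))   # (A, M)
    u = _iou_matrix(pred_boxes, gt_boxes)                            # (A, M)
    s = cls_scores[:, gt_cls].clip(min=1e-9)                         # (A, M)
    t = (s ** alpha) * (u ** beta)
    t = np.where(inside, t, 0.0)

    mask_pos = np.zeros((A, M), bool)
    k = min(topk, A)
    order = np.argsort(-t, axis=0)[:k]                               # (k, M)
    for m in range(M):
        cand = order[:, m]
        cand = cand[t[cand, m] > 0]
        mask_pos[cand, m] = True

    # a point claimed by several boxes goes to its highest-IoU claimant
    multi = mask_pos.sum(axis=1) > 1
    if multi.any():
        best = np.argmax(np.where(mask_pos, u, -1.0), axis=1)
        keep = np.zeros_like(mask_pos)
        keep[np.arange(A), best] = True
        mask_pos = np.where(multi[:, None], mask_pos & keep, mask_pos)

    fg_mask = mask_pos.any(axis=1)
    gt_idx = np.argmax(mask_pos, axis=1)

    # rescale alignment so each box's best point carries its best IoU
    t_pos = np.where(mask_pos, t, 0.0)
    u_pos = np.where(mask_pos, u, 0.0)
    t_max = t_pos.max(axis=0)
    u_max = u_pos.max(axis=0)
    norm = t_pos * (u_max / np.maximum(t_max, 1e-9))[None, :]
    target_scores = np.zeros((A, nc))
    fg = np.flatnonzero(fg_mask)
    target_scores[fg, gt_cls[gt_idx[fg]]] = norm[fg, gt_idx[fg]]
    target_boxes = gt_boxes[gt_idx]
    return AssignResult(fg_mask, gt_idx, target_scores, target_boxes)
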