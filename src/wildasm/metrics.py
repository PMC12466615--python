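"""Detection evaluation: IoU, NMS, PR/F1, COCO-style AP, confusion matrix.

Definitions:

* precision P = TP/(TP+FP), recall R = TP/(TP+FN), F1 = 2PR/(P+R);
* AP is the mean of the monotone (enveloped) interpolated precision at 101
  evenly spaced recall points;
* mAP50 is the unweighted mean of per-class AP at IoU 0.5 over classes with
  ground-truth support; mAP50-95 additionally averages over IoU thresholds
  0.50:0.05:0.95;
* the normalized confusion matrix has one extra background row/column —
  rows are predicted class, columns are true class, and each supported
  column sums to 1.

Summary P/R/F1 are reported at the F1-maximizing confidence over the PR
sweep, the convention detector frameworks print in their result tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Detection", "MetricsReport", "iou", "confidence_score", "nms",
    "match_detections", "precision_recall_f1", "average_precision",
    "map50", "map50_95", "confusion_matrix_normalized", "evaluate_detections",
]

IOU_THRESHOLDS_50_95 = np.round(np.arange(0.50, 0.96, 0.05), 2)


@dataclass(frozen=True)
class Detection:
    """A scored prediction: class, xyxy pixel box, confidence in [0, 1]."""

    class_id: int
    box: tuple
    confidence: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def iou(box_a, box_b) -> float:
    """Intersection area over union area of two xyxy boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError("boxes must have positive area (xyxy with x2>x1, y2>y1)")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def _iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a, b = np.asarray(boxes_a, float), np.asarray(boxes_b, float)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def confidence_score(p_object: float, iou_value: float) -> float:
    """Detection confidence: P(object present) x localization IoU."""
    for name, v in (("p_object", p_object), ("iou_value", iou_value)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return p_object * iou_value


def nms(detections, iou_threshold: float = 0.7, conf_threshold: float = 0.001) -> list:
    """Class-aware greedy non-maximum suppression."""
    dets = sorted((d for d in detections if d.confidence >= conf_threshold),
                  key=lambda d: -d.confidence)
    kept: list = []
    for d in dets:
        if all(k.class_id != d.class_id or iou(k.box, d.box) <= iou_threshold
               for k in kept):
            kept.append(d)
    return kept


def match_detections(detections, ground_truths, iou_threshold: float = 0.5):
    """Greedy per-class matching of detections (desc. confidence) to boxes.

    ``ground_truths``: sequence of (class_id, xyxy box).  Returns
    (tp_flags aligned with the confidence-sorted detections, that sorted
    detection list, fn_count).
    """
    dets = sorted(detections, key=lambda d: -d.confidence)
    gt_used = [False] * len(ground_truths)
    tp = np.zeros(len(dets), dtype=bool)
    for i, d in enumerate(dets):
        best_j, best_iou = -1, iou_threshold
        for j, (gcls, gbox) in enumerate(ground_truths):
            if gt_used[j] or gcls != d.class_id:
                continue
            v = iou(d.box, gbox)
            if v >= best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            gt_used[best_j] = True
            tp[i] = True
    fn = gt_used.count(False)
    return tp, dets, fn


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P, R and their harmonic mean; zero-denominator cases return 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _ap_from_curve(tp_sorted: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from confidence-ordered TP flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp_sorted) == 0:
        return 0.0
    tp_cum = np.cumsum(tp_sorted)
    fp_cum = np.cumsum(~tp_sorted)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone precision envelope, then sample 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    points = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, points, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def average_precision(matched, iou_threshold: float = 0.5) -> float:
    """AP for one class from pooled per-image (detections, ground truths).

    ``matched``: list of (detections, gt_boxes) pairs, one per image, all of
    a single class; gt_boxes are xyxy tuples.
    """
    flags, confs = [], []
    n_gt = 0
    for dets, gt_boxes, in matched:
        gts = [(dets[0].class_id if dets else 0, b) for b in gt_boxes]
        n_gt += len(gt_boxes)
        tp, sdets, _ = match_detections(dets, gts, iou_threshold)
        flags.extend(tp.tolist())
        confs.extend(d.confidence for d in sdets)
    if n_gt == 0:
        return float("nan")
    order = np.argsort(-np.asarray(confs)) if confs else np.array([], int)
    return _ap_from_curve(np.asarray(flags, bool)[order], n_gt)


def map50(per_class_ap: dict) -> float:
    vals = [v for v in per_class_ap.values() if not np.isnan(v)]
    if not vals:
        raise ValueError("no class with ground-truth support")
    return float(np.mean(vals))


def map50_95(per_class_ap_by_threshold: dict) -> float:
    """Mean over IoU thresholds 0.50:0.05:0.95, then over classes."""
    per_class = {}
    for cid, by_thr in per_class_ap_by_threshold.items():
        vals = [by_thr[t] for t in sorted(by_thr)]
        if not any(np.isnan(v) for v in vals):
            per_class[cid] = float(np.mean(vals))
    return map50(per_class)


def confusion_matrix_normalized(detections_per_image, ground_truths_per_image,
                                nc: int, conf_threshold: float = 0.25,
                                iou_threshold: float = 0.45) -> np.ndarray:
    """(nc+1)^2 column-normalized confusion matrix with a background slot.

    Rows index predicted class, columns true class; matching is by IoU
    (class-agnostic, greedy by overlap), so cross-class confusions land in
    off-diagonal cells; misses go to the background row, ghosts to the
    background column.
    """
    m = np.zeros((nc + 1, nc + 1))
    for dets, gts in zip(detections_per_image, ground_truths_per_image):
        dets = [d for d in dets if d.confidence >= conf_threshold]
        gt_cls = [g[0] for g in gts]
        gt_boxes = [g[1] for g in gts]
        ious = _iou_matrix([d.box for d in dets], gt_boxes)
        det_used = np.zeros(len(dets), bool)
        gt_used = np.zeros(len(gts), bool)
        pairs = np.argwhere(ious >= iou_threshold)
        for i, j in sorted(pairs, key=lambda p: -ious[p[0], p[1]]):
            if det_used[i] or gt_used[j]:
                continue
            det_used[i] = gt_used[j] = True
            m[dets[i].class_id, gt_cls[j]] += 1
        for j in np.flatnonzero(~gt_used):
            m[nc, gt_cls[j]] += 1
        for i in np.flatnonzero(~det_used):
            m[dets[i].class_id, nc] += 1
    support = m.sum(axis=0)
    out = np.zeros_like(m)
    nonzero = support > 0
    out[:, nonzero] = m[:, nonzero] / support[nonzero]
    return out


@dataclass
class MetricsReport:
    """Full evaluation summary for one detector on one labelled set."""

    per_class_ap50: dict
    per_class_ap50_95: dict
    precision: float
    recall: float
    f1: float
    map50: float
    map50_95: float
    confusion: np.ndarray
    nc: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = np.asarray(self.confusion).tolist()
        d["per_class_ap50"] = {str(k): (None if np.isnan(v) else float(v))
                               for k, v in self.per_class_ap50.items()}
        d["per_class_ap50_95"] = {str(k): (None if np.isnan(v) else float(v))
                                  for k, v in self.per_class_ap50_95.items()}
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    def plot_confusion(self, path, class_names=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        names = list(class_names or map(str, range(self.nc))) + ["background"]
        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(names), 1 + 0.6 * len(names)))
        im = ax.imshow(self.confusion, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(len(names)), names, rotation=90)
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("True")
        ax.set_ylabel("Predicted")
        for i in range(len(names)):
            for j in range(len(names)):
                v = self.confusion[i, j]
                if v >= 0.005:
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                            fontsize=7, color="white" if v > 0.5 else "black")
        fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def evaluate_detections(detections_per_image, ground_truths_per_image,
                        nc: int) -> MetricsReport:
    """Evaluate pooled per-image detections against (class_id, box) truths."""
    ap50: dict = {}
    ap_by_thr: dict = {cid: {} for cid in range(nc)}
    # per-class pooled TP flags at IoU 0.5, kept for the summary P/R sweep
    sweep: dict = {}
    for cid in range(nc):
        per_image = []
        for dets, gts in zip(detections_per_image, ground_truths_per_image):
            cls_dets = [d for d in dets if d.class_id == cid]
            cls_gts = [g[1] for g in gts if g[0] == cid]
            per_image.append((cls_dets, cls_gts))
        n_gt = sum(len(g) for _, g in per_image)
        for thr in IOU_THRESHOLDS_50_95:
            flags, confs = [], []
            for dets, gt_boxes in per_image:
                tp, sdets, _ = match_detections(
                    dets, [(cid, b) for b in gt_boxes], float(thr))
                flags.extend(tp.tolist())
                confs.extend(d.confidence for d in sdets)
            order = np.argsort(-np.asarray(confs)) if confs else np.array([], int)
            oflags = np.asarray(flags, bool)[order]
            ap_by_thr[cid][float(thr)] = _ap_from_curve(oflags, n_gt)
            if abs(thr - 0.5) < 1e-9:
                ap50[cid] = ap_by_thr[cid][float(thr)]
                sweep[cid] = (oflags, np.sort(np.asarray(confs))[::-1], n_gt)
    # summary P/R/F1 at the F1-maximizing confidence (macro over classes)
    precision, recall, f1 = _summary_prf(sweep)
    report = MetricsReport(
        per_class_ap50=ap50,
        per_class_ap50_95={cid: (float(np.mean(list(d.values())))
                                 if not any(np.isnan(v) for v in d.values())
                                 else float("nan"))
                           for cid, d in ap_by_thr.items()},
        precision=precision, recall=recall, f1=f1,
        map50=map50(ap50),
        map50_95=map50_95(ap_by_thr),
        confusion=confusion_matrix_normalized(
            detections_per_image, ground_truths_per_image, nc),
        nc=nc)
    return report


def _summary_prf(sweep: dict):
    """Macro-averaged P/R at the confidence maximizing the mean F1 curve."""
    supported = {c: v for c, v in sweep.items() if v[2] > 0}
    if not supported:
        return 0.0, 0.0, 0.0
    grid = np.unique(np.concatenate(
        [confs for _, confs, _ in supported.values()] or [np.array([0.5])]))
    if len(grid) == 0:
        return 0.0, 0.0, 0.0
    best = (0.0, 0.0, 0.0)
    for thr in grid:
        ps, rs = [], []
        for flags, confs, n_gt in supported.values():
            k = int(np.searchsorted(-confs, -thr, side="right"))
            tp = int(flags[:k].sum())
            fp = k - tp
            p, r, _ = precision_recall_f1(tp, fp, n_gt - tp)
            ps.append(p)
            rs.append(r)
        p, r = float(np.mean(ps)), float(np.mean(rs))
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best[2]:
            best = (p, r, f1)
    return best
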