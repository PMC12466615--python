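"""Training engine: SGD with momentum, warmup + one-cycle decay, and
validation-loss early stopping.

The stopping protocol is literal: training runs for at most ``max_epochs``
and halts once the validation loss has not improved for ``patience``
consecutive epochs; the returned weights are those of the best validation
epoch.  One seed controls weight initialization (via the model config),
batch shuffling and augmentation draws, so identical configurations
reproduce identical trajectories.
"""

from __future__ import annotations

import copy
import csv
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import DetectionDataset
from .losses import LossGains, total_loss
from .metrics import MetricsReport, evaluate_detections, nms
from .model import Detector, decode_predictions, save_checkpoint

__all__ = ["TrainConfig", "EarlyStopper", "SGD", "train_loop",
           "evaluate_model", "TrainResult"]


@dataclass
class TrainConfig:
    max_epochs: int = 5000
    patience: int = 50
    batch_size: int = 16
    workers: int = 8          # informational; loading is in-process
    lr0: float = 0.01
    lrf: float = 0.01         # final lr fraction of lr0 (one-cycle style)
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    gains: LossGains = field(default_factory=LossGains)
    augment_flip: float = 0.0  # probability of horizontal flip per sample
    grad_clip_norm: float = 10.0
    eval_every: int = 0        # compute mAP on the val set every k epochs
    seed: int = 0

    def __post_init__(self):
        if self.patience < 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience >= 0, max_epochs >= 1, batch_size >= 1 required")


class EarlyStopper:
    """Halt after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = math.inf
        self.best_epoch = 0
        self.since = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record an epoch's monitored value; returns True when to stop."""
        if value < self.best:
            self.best, self.best_epoch, self.since = value, epoch, 0
        else:
            self.since += 1
        return self.since >= self.patience


class SGD:
    """Momentum SGD; weight decay on matrix/conv weights only."""

    def __init__(self, model: Detector, cfg: TrainConfig):
        self.cfg = cfg
        self.params = list(model.named_parameters())
        self.velocity = {name: np.zeros_like(p.data) for name, p in self.params}
        self.lr = cfg.lr0

    def set_lr(self, lr: float):
        self.lr = lr

    def step(self):
        cfg = self.cfg
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            if p.data.ndim >= 2:
                g = g + cfg.weight_decay * p.data
            v = self.velocity[name]
            v *= cfg.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self):
        for _, p in self.params:
            p.zero_grad()


def _clip_gradients(model: Detector, max_norm: float):
    total = 0.0
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
    return norm


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        return cfg.lr0 * (epoch + 1) / cfg.warmup_epochs
    frac = epoch / max(cfg.max_epochs - 1, 1)
    return cfg.lr0 * (1.0 - frac * (1.0 - cfg.lrf))


@dataclass
class TrainResult:
    best_state: dict
    best_epoch: int
    stopped_epoch: int
    history: list          # per-epoch dict rows

    def restore_best(self, model: Detector):
        model.load_state_dict(self.best_state)
        return model


def _epoch_loss(model: Detector, dataset: DetectionDataset, cfg: TrainConfig,
                rng: np.random.Generator | None, optimizer: SGD | None):
    """One pass over the dataset; trains when an optimizer is given."""
    n = len(dataset)
    order = rng.permutation(n) if rng is not None else np.arange(n)
    totals = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
    n_batches = 0
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        flip = (rng.random(len(idx)) < cfg.augment_flip) if (
            rng is not None and cfg.augment_flip > 0) else None
        images, targets = dataset.batch(idx, flip)
        raw = model(images)
        loss, comps = total_loss(raw, targets, model, cfg.gains)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss {loss.data!r}; aborting")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            _clip_gradients(model, cfg.grad_clip_norm)
            optimizer.step()
        for k, v in comps.items():
            totals[k] += v
        totals["total"] += float(loss.data)
        n_batches += 1
    return {k: v / max(n_batches, 1) for k, v in totals.items()}


def train_loop(model: Detector, train_set: DetectionDataset,
               val_set: DetectionDataset, cfg: TrainConfig,
               out_dir=None, verbose: bool = False) -> TrainResult:
    """Train with validation-loss early stopping; returns the best epoch.

    Writes ``results.csv`` plus ``best.npz``/``last.npz`` checkpoints when
    ``out_dir`` is given.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = SGD(model, cfg)
    stopper = EarlyStopper(cfg.patience)
    best_state = model.state_dict()
    history = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    epoch = 0
    for epoch in range(cfg.max_epochs):
        optimizer.set_lr(_lr_at(cfg, epoch))
        model.train()
        t0 = time.time()
        train_stats = _epoch_loss(model, train_set, cfg, rng, optimizer)
        model.eval()
        val_stats = _epoch_loss(model, val_set, cfg, None, None) if len(val_set) \
            else {"total": train_stats["total"]}
        row = {"epoch": epoch, "lr": optimizer.lr,
               "box_loss": train_stats["box"], "cls_loss": train_stats["cls"],
               "dfl_loss": train_stats["dfl"], "train_loss": train_stats["total"],
               "val_loss": val_stats["total"], "seconds": time.time() - t0,
               "precision": float("nan"), "recall": float("nan"),
               "map50": float("nan"), "map50_95": float("nan")}
        if cfg.eval_every and (epoch + 1) % cfg.eval_every == 0 and len(val_set):
            report = evaluate_model(model, val_set)
            row.update(precision=report.precision, recall=report.recall,
                       map50=report.map50, map50_95=report.map50_95)
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: train {row['train_loss']:.4f} "
                  f"val {row['val_loss']:.4f}")
        improved = val_stats["total"] < stopper.best
        stop = stopper.update(epoch, val_stats["total"])
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    if out_dir is not None:
        with open(out_dir / "results.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
        meta = {"best_epoch": stopper.best_epoch, "stopped_epoch": epoch,
                "val_loss": stopper.best}
        save_checkpoint(out_dir / "last.npz", model, meta)
        current = model.state_dict()
        model.load_state_dict(best_state)
        save_checkpoint(out_dir / "best.npz", model, meta)
        model.load_state_dict(current)
    return TrainResult(best_state, stopper.best_epoch, epoch, history)


def evaluate_model(model: Detector, dataset: DetectionDataset,
                   conf_threshold: float = 0.001, nms_iou: float = 0.7,
                   batch_size: int = 8) -> MetricsReport:
    """Forward + decode + NMS + metrics over a dataset."""
    model.eval()
    detections = []
    for start in range(0, len(dataset), batch_size):
        idx = range(start, min(start + batch_size, len(dataset)))
        images, _ = dataset.batch(list(idx))
        raw = model(images)
        for dets in decode_predictions(raw, model.cfg, conf_threshold):
            detections.append(nms(dets, nms_iou, conf_threshold))
    return evaluate_detections(detections, dataset.ground_truths(), dataset.nc)
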