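"""Detector assembly: baseline three-scale model and the WildASM variant.

The baseline is a nano-scale anchor-free detector: a C2f/SPPF backbone, a
PAN-FPN neck, and decoupled heads at strides {8, 16, 32}.  The WildASM
variant adds (i) a multi-head self-attention block after the SPPF, (ii) an
extended top-down path down to stride 4 (P2, 160x160 at 640 input) with a
fourth detection head for ultra-small targets, and (iii) learnable weighted
fusion nodes in place of plain concatenations — two-input nodes on the
top-down path, three-input nodes on the bottom-up path where backbone,
top-down and downsampled features meet.

Complexity accounting follows the conventions detector summaries print:
parameters are reported for the deploy-time (conv+BN folded) model, and
GFLOPs as 2x multiply–accumulates of convolution and linear layers on one
3 x input_size x input_size pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .attention import MultiHeadSelfAttention
from .autograd import Tensor, concat
from .fusion import BiFPNConcat
from .layers import (C2f, Conv, Conv2dBias, Module, SPPF, Upsample,
                     scale_channels, scale_depth)

VARIANTS = ("baseline", "wildasm")
BASE_CHANNELS = (64, 128, 256, 512, 1024)
BASE_DEPTHS = (3, 6, 6, 3)


@dataclass
class ModelConfig:
    variant: str = "baseline"
    nc: int = 10
    width_mult: float = 0.25
    depth_mult: float = 0.33
    max_channels: int = 1024
    reg_max: int = 16
    mhsa_heads: int = 4
    mhsa_residual: bool = False
    input_size: int = 640
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.nc < 1:
            raise ValueError("nc must be >= 1")
        if self.input_size % 32:
            raise ValueError(f"input_size must be a multiple of 32, got {self.input_size}")
        if self.reg_max < 2:
            raise ValueError("reg_max must be >= 2")

    @property
    def channels(self) -> tuple:
        return tuple(scale_channels(b, self.width_mult, self.max_channels)
                     for b in BASE_CHANNELS)

    @property
    def depths(self) -> tuple:
        return tuple(scale_depth(b, self.depth_mult) for b in BASE_DEPTHS)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComplexityReport:
    n_params: int
    gflops: float
    n_layers: int
    size_mb: float

    def to_dict(self) -> dict:
        return asdict(self)


class DetectHead(Module):
    """Decoupled anchor-free head: per scale, a box-distribution branch
    (4 * reg_max channels) and a classification branch (nc channels)."""

    def __init__(self, rng, nc: int, ch: tuple, reg_max: int, strides: tuple):
        super().__init__()
        self.nc, self.reg_max, self.strides = nc, reg_max, strides
        cb = max(16, ch[0] // 4, 4 * reg_max)
        cc = max(ch[0], min(nc, 100))
        self.box_branch = [[Conv(rng, c, cb, 3), Conv(rng, cb, cb, 3),
                            Conv2dBias(rng, cb, 4 * reg_max, 1)] for c in ch]
        self.cls_branch = [[Conv(rng, c, cc, 3), Conv(rng, cc, cc, 3),
                            Conv2dBias(rng, cc, nc, 1)] for c in ch]
        # the fixed expectation weights of the distribution decoder
        self.dfl_proj = Tensor(np.arange(reg_max, dtype=np.float32))
        self._init_biases()

    def _init_biases(self):
        # prior-aware logit init so early training is not swamped by the
        # background term; standard practice for dense one-stage detectors
        for branch, s in zip(self.cls_branch, self.strides):
            branch[-1].bias.data[:] = math.log(5.0 / self.nc / (640.0 / s) ** 2)
        for branch in self.box_branch:
            branch[-1].bias.data[:] = 1.0

    def forward(self, feats):
        out = {}
        for (f, s, bb, cb) in zip(feats, self.strides, self.box_branch, self.cls_branch):
            box = f
            for m in bb:
                box = m(box)
            cls = f
            for m in cb:
                cls = m(cls)
            out[s] = (box, cls)
        return out


class Detector(Module):
    """The assembled detector; ``forward`` maps an image batch to per-stride
    raw predictions ``{stride: (box_logits, cls_logits)}``."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3, c4, c5 = cfg.channels
        n1, n2, n2b, n1b = cfg.depths  # (3,6,6,3)-ladder scaled

        # backbone
        self.stem = Conv(rng, 3, c1, 3, 2)                      # P1/2
        self.down2 = Conv(rng, c1, c2, 3, 2)                    # P2/4
        self.stage2 = C2f(rng, c2, c2, n1, True)
        self.down3 = Conv(rng, c2, c3, 3, 2)                    # P3/8
        self.stage3 = C2f(rng, c3, c3, n2, True)
        self.down4 = Conv(rng, c3, c4, 3, 2)                    # P4/16
        self.stage4 = C2f(rng, c4, c4, n2b, True)
        self.down5 = Conv(rng, c4, c5, 3, 2)                    # P5/32
        self.stage5 = C2f(rng, c5, c5, n1b, True)
        self.sppf = SPPF(rng, c5, c5, 5)

        self.up = Upsample()
        wild = cfg.variant == "wildasm"
        if wild:
            self.mhsa = MultiHeadSelfAttention(rng, c5, cfg.mhsa_heads,
                                               cfg.mhsa_residual)
        # top-down path
        self.td4 = C2f(rng, c5 + c4, c4, n1b)
        self.td3 = C2f(rng, c4 + c3, c3, n1b)
        if wild:
            self.fuse_td4 = BiFPNConcat(2)
            self.fuse_td3 = BiFPNConcat(2)
            self.fuse_td2 = BiFPNConcat(2)
            self.td2 = C2f(rng, c3 + c2, c2, n1b)
            # bottom-up path with three-way fusion where backbone, top-down
            # and downsampled features meet
            self.bu_down2 = Conv(rng, c2, c2, 3, 2)
            self.fuse_bu3 = BiFPNConcat(3)
            self.bu3 = C2f(rng, c2 + 2 * c3, c3, n1b)
            self.bu_down3 = Conv(rng, c3, c3, 3, 2)
            self.fuse_bu4 = BiFPNConcat(3)
            self.bu4 = C2f(rng, c3 + 2 * c4, c4, n1b)
            self.bu_down4 = Conv(rng, c4, c4, 3, 2)
            self.fuse_bu5 = BiFPNConcat(2)
            self.bu5 = C2f(rng, c4 + c5, c5, n1b)
            self.strides = (4, 8, 16, 32)
            head_ch = (c2, c3, c4, c5)
        else:
            self.bu_down3 = Conv(rng, c3, c3, 3, 2)
            self.bu4 = C2f(rng, c3 + c4, c4, n1b)
            self.bu_down4 = Conv(rng, c4, c4, 3, 2)
            self.bu5 = C2f(rng, c4 + c5, c5, n1b)
            self.strides = (8, 16, 32)
            head_ch = (c3, c4, c5)
        self.head = DetectHead(rng, cfg.nc, head_ch, cfg.reg_max, self.strides)

    # -- inference graph ------------------------------------------------------
    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, c, h, w = x.shape
        if c != 3 or h != self.cfg.input_size or w != self.cfg.input_size:
            raise ValueError(
                f"expected 3x{self.cfg.input_size}x{self.cfg.input_size} input "
                f"(letterbox first), got {c}x{h}x{w}")
        p1 = self.stem(x)
        p2 = self.stage2(self.down2(p1))
        p3 = self.stage3(self.down3(p2))
        p4 = self.stage4(self.down4(p3))
        p5 = self.sppf(self.stage5(self.down5(p4)))
        if self.cfg.variant == "wildasm":
            p5 = self.mhsa(p5)
            t4 = self.td4(self.fuse_td4([self.up(p5), p4]))
            t3 = self.td3(self.fuse_td3([self.up(t4), p3]))
            t2 = self.td2(self.fuse_td2([self.up(t3), p2]))
            b3 = self.bu3(self.fuse_bu3([self.bu_down2(t2), t3, p3]))
            b4 = self.bu4(self.fuse_bu4([self.bu_down3(b3), t4, p4]))
            b5 = self.bu5(self.fuse_bu5([self.bu_down4(b4), p5]))
            feats = (t2, b3, b4, b5)
        else:
            t4 = self.td4(concat([self.up(p5), p4], axis=1))
            t3 = self.td3(concat([self.up(t4), p3], axis=1))
            b4 = self.bu4(concat([self.bu_down3(t3), t4], axis=1))
            b5 = self.bu5(concat([self.bu_down4(b4), p5], axis=1))
            feats = (t3, b4, b5)
        return self.head(feats)


def build_model(cfg: ModelConfig) -> Detector:
    return Detector(cfg)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

def count_parameters(model: Detector, fuse: bool = True) -> int:
    """Exact parameter count, including the fixed distribution-decoder
    projection; running statistics excluded.

    With ``fuse=True`` (default, and what summary tables conventionally
    print) each conv+BN pair is counted in its deploy-time folded form —
    conv weight plus a bias absorbing the normalization affine.
    """
    total = sum(p.data.size for p in model.parameters())
    total += model.head.dfl_proj.data.size
    if fuse:
        for m in model.modules():
            if isinstance(m, Conv):
                total -= m.c2  # weight + 2 affine vectors -> weight + bias
    return int(total)


def _conv_macs(m, h: int, w: int):
    """(MACs, out_channels, out_h, out_w) for one conv cell."""
    p = m.k // 2
    ho = (h + 2 * p - m.k) // m.s + 1
    wo = (w + 2 * p - m.k) // m.s + 1
    return m.k * m.k * m.c1 * m.c2 * ho * wo, m.c2, ho, wo


def _c2f_macs(m: C2f, h: int, w: int) -> int:
    macs, _, _, _ = _conv_macs(m.cv1, h, w)
    for b in m.m:
        macs += _conv_macs(b.cv1, h, w)[0] + _conv_macs(b.cv2, h, w)[0]
    macs += _conv_macs(m.cv2, h, w)[0]
    return macs


def count_flops(model: Detector, input_size: int | None = None) -> float:
    """GFLOPs = 2 x multiply–accumulates of conv and linear layers at
    1 x 3 x input_size x input_size, to one decimal."""
    cfg = model.cfg
    s = input_size or cfg.input_size
    if s % 32:
        raise ValueError("input_size must be a multiple of 32")
    macs = 0
    h = w = s

    def conv(m):
        nonlocal macs, h, w
        mm, _, h, w = _conv_macs(m, h, w)
        macs += mm

    conv(model.stem)
    conv(model.down2); macs += _c2f_macs(model.stage2, h, w)
    conv(model.down3); macs += _c2f_macs(model.stage3, h, w)
    h3 = w3 = h
    conv(model.down4); macs += _c2f_macs(model.stage4, h, w)
    h4 = w4 = h
    conv(model.down5); macs += _c2f_macs(model.stage5, h, w)
    h5 = w5 = h
    macs += _conv_macs(model.sppf.cv1, h5, w5)[0] + _conv_macs(model.sppf.cv2, h5, w5)[0]
    wild = cfg.variant == "wildasm"
    if wild:
        n_tok = h5 * w5
        macs += 4 * n_tok * model.mhsa.d * model.mhsa.d  # the four linear projections
    macs += _c2f_macs(model.td4, h4, w4)
    macs += _c2f_macs(model.td3, h3, w3)
    if wild:
        h2 = w2 = 2 * h3
        macs += _c2f_macs(model.td2, h2, w2)
        macs += _conv_macs(model.bu_down2, h2, w2)[0]
        macs += _c2f_macs(model.bu3, h3, w3)
        macs += _conv_macs(model.bu_down3, h3, w3)[0]
        macs += _c2f_macs(model.bu4, h4, w4)
        macs += _conv_macs(model.bu_down4, h4, w4)[0]
        macs += _c2f_macs(model.bu5, h5, w5)
        sizes = (h2, h3, h4, h5)
    else:
        macs += _conv_macs(model.bu_down3, h3, w3)[0]
        macs += _c2f_macs(model.bu4, h4, w4)
        macs += _conv_macs(model.bu_down4, h4, w4)[0]
        macs += _c2f_macs(model.bu5, h5, w5)
        sizes = (h3, h4, h5)
    for bb, cb, hs in zip(model.head.box_branch, model.head.cls_branch, sizes):
        for m in bb + cb:
            macs += _conv_macs(m, hs, hs)[0]
    return round(2 * macs / 1e9, 1)


def count_layers(model: Detector) -> int:
    """Leaf-module count; informational only (summary-table conventions for
    'layers' vary across frameworks)."""
    leaves = 0
    for m in model.modules():
        if isinstance(m, (Conv, Conv2dBias, Upsample, BiFPNConcat,
                          MultiHeadSelfAttention)):
            leaves += 1
    return leaves


def complexity_report(model: Detector, input_size: int | None = None) -> ComplexityReport:
    n = count_parameters(model)
    return ComplexityReport(
        n_params=n,
        gflops=count_flops(model, input_size),
        n_layers=count_layers(model),
        size_mb=round(n * 2 / 1e6, 1),  # half-precision deploy serialization
    )


# ---------------------------------------------------------------------------
# decoding and checkpoints
# ---------------------------------------------------------------------------

def dfl_expectation(box_logits: np.ndarray, reg_max: int) -> np.ndarray:
    """Expected side offsets (in grid cells) of the reg_max-bin distributions.

    ``box_logits``: (n, 4*reg_max, h, w) -> (n, 4, h, w) expectations.
    """
    n, c, h, w = box_logits.shape
    d = box_logits.reshape(n, 4, reg_max, h, w)
    d = d - d.max(axis=2, keepdims=True)
    e = np.exp(d)
    prob = e / e.sum(axis=2, keepdims=True)
    bins = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1, 1)
    return (prob * bins).sum(axis=2)


def decode_predictions(raw: dict, cfg: ModelConfig, conf_threshold: float = 0.25):
    """Raw per-stride logits -> per-image detection arrays in pixel coords.

    Returns, per image, ``(boxes_xyxy, scores, class_ids)``; scores are
    sigmoid class probabilities, rows below ``conf_threshold`` dropped.
    """
    from .metrics import Detection  # local import; metrics is model-free

    per_image = None
    for stride, (box_t, cls_t) in raw.items():
        box = box_t.data if isinstance(box_t, Tensor) else np.asarray(box_t)
        cls = cls_t.data if isinstance(cls_t, Tensor) else np.asarray(cls_t)
        n, _, h, w = box.shape
        if per_image is None:
            per_image = [[] for _ in range(n)]
        ltrb = dfl_expectation(box, cfg.reg_max) * stride  # pixels
        ys, xs = np.mgrid[0:h, 0:w]
        cx = (xs + 0.5) * stride
        cy = (ys + 0.5) * stride
        x1 = cx - ltrb[:, 0]
        y1 = cy - ltrb[:, 1]
        x2 = cx + ltrb[:, 2]
        y2 = cy + ltrb[:, 3]
        prob = 0.5 * (1.0 + np.tanh(0.5 * cls))
        best = prob.argmax(axis=1)
        score = prob.max(axis=1)
        for i in range(n):
            keep = score[i] >= conf_threshold
            if not keep.any():
                continue
            for b0, b1, b2, b3, sc, cid in zip(
                    x1[i][keep], y1[i][keep], x2[i][keep], y2[i][keep],
                    score[i][keep], best[i][keep]):
                if b2 > b0 and b3 > b1:
                    per_image[i].append(Detection(
                        class_id=int(cid),
                        box=(float(b0), float(b1), float(b2), float(b3)),
                        confidence=float(sc)))
    return per_image or []


def save_checkpoint(path, model: Detector, metadata: dict | None = None):
    """Single-file checkpoint: weights + config echo + training metadata."""
    state = model.state_dict()
    meta = {"config": model.cfg.to_dict(), "metadata": metadata or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta["metadata"]
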