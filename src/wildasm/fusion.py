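"""Learnable weighted feature fusion (BiFPN_Concat2 / BiFPN_Concat3).

Each fusion node carries one nonnegative learnable weight per input map.
Raw weights pass through max(., 0) and are normalized as

    weight_i = w_i / (sum_j w_j + eps),    eps = 0.01,

so the normalized weights are nonnegative and sum to strictly less than 1;
the small constant keeps the node well-defined at the all-zero point.  The
scaled maps are then concatenated along the channel axis, which preserves
spatial size and lets the following block mix them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Tensor, as_tensor, concat, relu
from .layers import Module

__all__ = ["FusionWeights", "normalize_fusion_weights", "bifpn_concat", "BiFPNConcat"]

DEFAULT_EPS = 0.01


@dataclass
class FusionWeights:
    """Nonnegative per-input fusion weights for a k-way fusion node (k in {2,3})."""

    values: Sequence[float]
    epsilon: float = DEFAULT_EPS

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or len(vals) not in (2, 3):
            raise ValueError("fusion nodes take 2 or 3 inputs")
        for i, v in enumerate(vals):
            if not np.isfinite(v):
                raise ValueError(f"non-finite fusion weight at index {i}: {v!r}")
        if (vals < 0).any():
            raise ValueError("fusion weights must be nonnegative (apply max(.,0) first)")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        self.values = tuple(float(v) for v in vals)


def normalize_fusion_weights(w: FusionWeights) -> tuple:
    """weight_i = w_i / (sum_j w_j + eps); outputs sum to sum(w)/(sum(w)+eps) < 1."""
    vals = np.asarray(w.values, dtype=np.float64)
    return tuple(vals / (vals.sum() + w.epsilon))


def bifpn_concat(maps, w: FusionWeights):
    """Scale each map by its normalized weight, then concatenate on channels.

    ``maps`` are C x H x W (or N x C x H x W) grids sharing spatial size; the
    output has the summed channel count and unchanged spatial size.
    """
    maps = [as_tensor(m) for m in maps]
    if len(maps) != len(w.values):
        raise ValueError(f"{len(maps)} maps but {len(w.values)} fusion weights")
    spatial = {m.shape[-2:] for m in maps}
    if len(spatial) != 1:
        raise ValueError(f"fused maps must share spatial size, got {sorted(spatial)}")
    weights = normalize_fusion_weights(w)
    return concat([m * float(wi) for m, wi in zip(maps, weights)],
                  axis=maps[0].ndim - 3)


class BiFPNConcat(Module):
    """Trainable fusion node: k raw weights (init 1) -> relu -> normalize -> concat.

    The relu enforces the nonnegativity the normalization presumes while
    keeping the raw parameters freely trainable.
    """

    def __init__(self, k: int, epsilon: float = DEFAULT_EPS):
        super().__init__()
        if k not in (2, 3):
            raise ValueError("fusion nodes take 2 or 3 inputs")
        self.k = k
        self.epsilon = epsilon
        self.w = Tensor(np.ones(k), requires_grad=True)

    def forward(self, maps):
        if len(maps) != self.k:
            raise ValueError(f"node fuses {self.k} maps, got {len(maps)}")
        wpos = relu(self.w)
        norm = wpos / (wpos.sum() + self.epsilon)
        scaled = [m * norm[i] for i, m in enumerate(maps)]
        return concat(scaled, axis=1)

    def fusion_weights(self) -> FusionWeights:
        return FusionWeights(np.maximum(self.w.data, 0.0).tolist(), self.epsilon)
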