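"""Multi-head self-attention over flattened spatial positions.

Tokens are the H*W positions of a feature grid; each token attends to all
others through h parallel scaled-dot-product heads:

    Q = X Wq,  K = X Wk,  V = X Wv              (per-token linear maps)
    Head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i  (d_k = d / h)
    MHSA(X) = Concat(Head_1, ..., Head_h) Wo

All four projection matrices are d x d (so the output keeps the input
shape), carry no bias, and there is no positional encoding — the block is
therefore permutation-equivariant over spatial positions.  A residual
connection around the block is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concat, softmax
from .layers import Module, kaiming

__all__ = [
    "TokenMatrix", "AttentionParams", "qkv_project", "split_heads",
    "attention_scores", "attention_weights", "mhsa", "mhsa_spatial_block",
    "MultiHeadSelfAttention",
]


@dataclass
class TokenMatrix:
    """N x d token matrix (N flattened spatial positions, d channels)."""

    X: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or min(self.X.shape) < 1:
            raise ValueError(f"token matrix must be N x d, got shape {self.X.shape}")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class AttentionParams:
    """Projection matrices and head layout for one attention block."""

    d: int
    h: int
    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray

    def __post_init__(self):
        if self.d < 1 or self.h < 1:
            raise ValueError("d and h must be positive")
        if self.d % self.h:
            raise ValueError(f"d={self.d} not divisible by h={self.h}")
        for name in ("Wq", "Wk", "Wv", "Wo"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if m.shape != (self.d, self.d):
                raise ValueError(f"{name} must be {self.d}x{self.d}, got {m.shape}")
            setattr(self, name, m)

    @property
    def d_k(self) -> int:
        return self.d // self.h

    @classmethod
    def identity(cls, d: int, h: int = 1) -> "AttentionParams":
        eye = np.eye(d)
        return cls(d, h, eye, eye.copy(), eye.copy(), eye.copy())

    @classmethod
    def random(cls, d: int, h: int, rng: np.random.Generator) -> "AttentionParams":
        def m():
            return rng.normal(scale=d ** -0.5, size=(d, d))
        return cls(d, h, m(), m(), m(), m())


def qkv_project(X: TokenMatrix, p: AttentionParams):
    """Row-wise linear projections of each token into query/key/value space."""
    if X.d != p.d:
        raise ValueError(f"token dim {X.d} does not match projection dim {p.d}")
    return X.X @ p.Wq, X.X @ p.Wk, X.X @ p.Wv


def split_heads(M: np.ndarray, h: int):
    """Partition the feature dimension into h contiguous N x (d/h) blocks."""
    M = np.asarray(M)
    d = M.shape[-1]
    if d % h:
        raise ValueError(f"feature dim {d} not divisible by {h} heads")
    return [M[..., i * (d // h):(i + 1) * (d // h)] for i in range(h)]


def attention_scores(Qi: np.ndarray, Ki: np.ndarray, d_k: int) -> np.ndarray:
    """Scaled dot-product similarity: Q K^T / sqrt(d_k)."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Qi, Ki = np.asarray(Qi), np.asarray(Ki)
    if Qi.shape[-1] != Ki.shape[-1]:
        raise ValueError("query/key dimension mismatch")
    return Qi @ Ki.T / np.sqrt(d_k)


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Row-stochastic softmax of the score matrix (row-max stabilized)."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("attention scores must be finite")
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mhsa(X: TokenMatrix, p: AttentionParams) -> np.ndarray:
    """Full multi-head self-attention on a token matrix; output is N x d."""
    Q, K, V = qkv_project(X, p)
    heads = []
    for Qi, Ki, Vi in zip(split_heads(Q, p.h), split_heads(K, p.h), split_heads(V, p.h)):
        A = attention_weights(attention_scores(Qi, Ki, p.d_k))
        heads.append(A @ Vi)
    return np.concatenate(heads, axis=-1) @ p.Wo


def mhsa_spatial_block(F: np.ndarray, p: AttentionParams, residual: bool = False) -> np.ndarray:
    """Apply ``mhsa`` to a C x H x W grid by flattening positions to tokens."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError(f"expected C x H x W grid, got shape {F.shape}")
    c, h, w = F.shape
    if c != p.d:
        raise ValueError(f"grid has {c} channels but attention dim is {p.d}")
    tokens = TokenMatrix(F.reshape(c, h * w).T)
    out = mhsa(tokens, p)
    if residual:
        out = out + tokens.X
    return out.T.reshape(c, h, w)


class MultiHeadSelfAttention(Module):
    """Trainable MHSA block operating on N x C x H x W feature tensors."""

    def __init__(self, rng, d: int, h: int = 4, residual: bool = False):
        super().__init__()
        if d % h:
            raise ValueError(f"d={d} not divisible by h={h}")
        self.d, self.h, self.residual = d, h, residual
        self.Wq = kaiming(rng, (d, d), d)
        self.Wk = kaiming(rng, (d, d), d)
        self.Wv = kaiming(rng, (d, d), d)
        self.Wo = kaiming(rng, (d, d), d)

    def forward(self, x):
        x = as_tensor(x)
        n, c, hh, ww = x.shape
        if c != self.d:
            raise ValueError(f"input has {c} channels, block expects {self.d}")
        dk = self.d // self.h
        tokens = x.reshape(n, c, hh * ww).transpose(0, 2, 1)  # n, N, d
        q = tokens @ self.Wq
        k = tokens @ self.Wk
        v = tokens @ self.Wv
        heads = []
        for i in range(self.h):
            sl = slice(i * dk, (i + 1) * dk)
            scores = (q[:, :, sl] @ k[:, :, sl].transpose(0, 2, 1)) * (dk ** -0.5)
            heads.append(softmax(scores, axis=-1) @ v[:, :, sl])
        out = concat(heads, axis=2) @ self.Wo
        if self.residual:
            out = out + tokens
        return out.transpose(0, 2, 1).reshape(n, c, hh, ww)

    def params(self) -> AttentionParams:
        return AttentionParams(self.d, self.h, self.Wq.data.astype(np.float64),
                               self.Wk.data.astype(np.float64),
                               self.Wv.data.astype(np.float64),
                               self.Wo.data.astype(np.float64))
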