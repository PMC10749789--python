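"""Position-embedding fusion and the spot-sequence transformer encoder.

Each section is one token sequence: one token per spot.  A spot's token is
the concatenation of its capsule-derived visual feature with two learned
lookup embeddings indexed by the integer array coordinates (E_x[array_x],
E_y[array_y]), linearly projected to ``d_model``.  The encoder is a stack
of pre-norm residual blocks: multi-head self-attention over the section's
spots followed by a GELU feed-forward (expansion 4).  With all projection
weights at zero the residual paths make the encoder the identity map.

Position enters only through the embeddings, so the encoder is equivariant
to spot (token) order.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .io import SpotTable

__all__ = ["PositionEmbedding", "embed_positions", "fuse",
           "AttentionParams", "multi_head_attention", "ViTEncoder"]


class PositionEmbedding:
    """Learned lookup tables over integer array coordinates."""

    def __init__(self, max_x: int, max_y: int, d: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d = d
        self.E_x = Tensor(rng.normal(0, 0.02, size=(max_x + 1, d)),
                          requires_grad=True)
        self.E_y = Tensor(rng.normal(0, 0.02, size=(max_y + 1, d)),
                          requires_grad=True)

    def parameters(self) -> list:
        return [self.E_x, self.E_y]


def embed_positions(spots: SpotTable, tables: PositionEmbedding) -> Tensor:
    """Per-spot concat(E_x[array_x], E_y[array_y]), shape (N, 2d)."""
    if spots.array_x.max() >= tables.E_x.shape[0]:
        raise ValueError(
            f"array_x {int(spots.array_x.max())} exceeds embedding table "
            f"size {tables.E_x.shape[0]}")
    if spots.array_y.max() >= tables.E_y.shape[0]:
        raise ValueError(
            f"array_y {int(spots.array_y.max())} exceeds embedding table "
            f"size {tables.E_y.shape[0]}")
    ex = tables.E_x[spots.array_x]
    ey = tables.E_y[spots.array_y]
    return concat([ex, ey], axis=1)


def fuse(s_caps: Tensor, pos: Tensor, W_fuse: Tensor, b_fuse: Tensor) -> Tensor:
    """Concatenate visual features with position embeddings and project.

    s_caps: (N, d_f) capsule features; pos: (N, 2d) embeddings; output
    (N, d_model) token sequence.
    """
    s_caps = s_caps if isinstance(s_caps, Tensor) else Tensor(s_caps)
    pos = pos if isinstance(pos, Tensor) else Tensor(pos)
    if s_caps.shape[0] != pos.shape[0]:
        raise ValueError(
            f"feature rows {s_caps.shape[0]} != position rows {pos.shape[0]}")
    return concat([s_caps, pos], axis=1) @ W_fuse + b_fuse


class AttentionParams:
    """Per-head Q/K/V projections plus the head-merge matrix W_h."""

    def __init__(self, d_model: int, m: int,
                 rng: np.random.Generator | None = None):
        if d_model % m:
            raise ValueError(f"d_model {d_model} not divisible by heads {m}")
        rng = rng or np.random.default_rng(0)
        self.d_model, self.m = d_model, m
        self.d_k = d_model // m
        s = np.sqrt(1.0 / d_model)

        def mk():
            return Tensor(rng.normal(0, s, size=(m, d_model, self.d_k)),
                          requires_grad=True)

        self.W_Q, self.W_K, self.W_V = mk(), mk(), mk()
        self.W_h = Tensor(rng.normal(0, s, size=(d_model, d_model)),
                          requires_grad=True)

    def parameters(self) -> list:
        return [self.W_Q, self.W_K, self.W_V, self.W_h]


def multi_head_attention(X: Tensor, params: AttentionParams,
                         return_weights: bool = False):
    """softmax(QKᵀ/√d_k)V per head, heads concatenated and merged by W_h.

    X: (N, d_model) token sequence for one section.  Each attention row is
    a probability distribution over the N spots.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    m, d_k = params.m, params.d_k
    Xb = X.reshape(1, *X.shape)                 # broadcast over heads
    Q = Xb @ params.W_Q                         # (m, N, d_k)
    K = Xb @ params.W_K
    V = Xb @ params.W_V
    scores = (Q @ K.transpose(0, 2, 1)) * (1.0 / np.sqrt(d_k))
    A = scores.softmax(axis=-1)                 # (m, N, N)
    heads = A @ V                               # (m, N, d_k)
    N = X.shape[0]
    merged = heads.transpose(1, 0, 2).reshape(N, m * d_k) @ params.W_h
    return (merged, A) if return_weights else merged


class _Block:
    """One pre-norm residual block: LN → MHA → +x, LN → FF(GELU) → +x."""

    def __init__(self, d_model: int, m: int, rng: np.random.Generator,
                 ff_mult: int = 4):
        self.attn = AttentionParams(d_model, m, rng=rng)
        s = np.sqrt(1.0 / d_model)
        self.W1 = Tensor(rng.normal(0, s, size=(d_model, ff_mult * d_model)),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(ff_mult * d_model), requires_grad=True)
        self.W2 = Tensor(rng.normal(0, s / np.sqrt(ff_mult),
                                    size=(ff_mult * d_model, d_model)),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(d_model), requires_grad=True)
        self.g1 = Tensor(np.ones(d_model), requires_grad=True)
        self.c1 = Tensor(np.zeros(d_model), requires_grad=True)
        self.g2 = Tensor(np.ones(d_model), requires_grad=True)
        self.c2 = Tensor(np.zeros(d_model), requires_grad=True)

    def parameters(self) -> list:
        return (self.attn.parameters()
                + [self.W1, self.b1, self.W2, self.b2,
                   self.g1, self.c1, self.g2, self.c2])

    @staticmethod
    def _layer_norm(x: Tensor, g: Tensor, c: Tensor, eps: float = 1e-6) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + eps) ** 0.5) * g + c

    def __call__(self, x: Tensor) -> Tensor:
        x = x + multi_head_attention(self._layer_norm(x, self.g1, self.c1),
                                     self.attn)
        h = self._layer_norm(x, self.g2, self.c2)
        return x + (h @ self.W1 + self.b1).gelu() @ self.W2 + self.b2


class ViTEncoder:
    """Stack of ``depth`` pre-norm transformer blocks over a spot sequence."""

    def __init__(self, d_model: int, depth: int = 2, heads: int = 4,
                 rng: np.random.Generator | None = None):
        if depth < 1:
            raise ValueError("encoder depth must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.d_model = d_model
        self.blocks = [_Block(d_model, heads, rng) for _ in range(depth)]

    def parameters(self) -> list:
        return [p for b in self.blocks for p in b.parameters()]

    def __call__(self, seq: Tensor) -> Tensor:
        x = seq if isinstance(seq, Tensor) else Tensor(seq)
        for b in self.blocks:
            x = b(x)
        return x
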