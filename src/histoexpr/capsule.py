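"""Capsule stage: primary capsules, squash activation, self-attention routing.

A capsule is a small activity vector whose norm encodes the presence of an
entity and whose direction encodes its pose.  The stage maps a convolutional
feature map to ``n`` primary capsules of dimension ``d`` (ReLU convolution
followed by a depthwise convolution and a reshape), squashes them with the
exponential norm-bounding nonlinearity

    u = (1 - e^{-||s||}) * s / ||s||,

then routes them to ``n'`` output capsules.  Routing is agreement-based:
each input capsule emits a prediction U_{ij} for every output capsule
(Eq-style per-capsule weight matrices), pairwise agreement between the
predictions aimed at the same output capsule forms logits, a softmax over
the *output-capsule* axis turns them into coupling coefficients C, and the
next layer's pre-activation is the (C + B)-weighted sum of predictions with
B a learned log-prior matrix initialised to zero.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["squash", "primary_capsules", "predict_capsules",
           "coupling_coefficients", "route", "CapsuleStage"]

# guard for the norm divisor at s = 0: added under the square root, so the
# norm (and the squash value) is exact to float precision away from zero
_EPS = 1e-30


def squash(s: Tensor | np.ndarray) -> Tensor:
    """Norm-bounding capsule nonlinearity, applied along the last axis.

    ``u = (1 - exp(-||s||)) * s/||s||``; the norm of the output lies in
    [0, 1) and ``squash(0) = 0`` by the continuous limit (guarded with a
    small epsilon in the divisor).
    """
    s = s if isinstance(s, Tensor) else Tensor(s)
    nrm = s.norm(axis=-1, keepdims=True, eps=_EPS)
    scale = (1.0 - (-nrm).exp()) / nrm
    return s * scale


def primary_capsules(feature_map, conv_w: Tensor, depth_w: Tensor,
                     caps_dim: int) -> Tensor:
    """Map a (B, C, H, W) feature map to (B, n, d) primary capsules.

    ReLU(Conv_{k×k}) with ``conv_w`` (C→C, stride 1, same padding), then a
    per-channel (depthwise) k×k convolution with ``depth_w`` of shape
    (C, 1, k, k), then a reshape of the flattened (C·H·W) activations into
    capsules of dimension ``caps_dim``.
    """
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    B, C, H, W = x.shape
    k = conv_w.shape[-1]
    f = x.conv2d(conv_w, padding=k // 2).relu()
    # depthwise: convolve each channel independently
    kd = depth_w.shape[-1]
    chans = [f[:, c:c + 1].conv2d(depth_w[c:c + 1], padding=kd // 2)
             for c in range(C)]
    from .autograd import concat
    g = concat(chans, axis=1)                      # (B, C, H, W)
    flat = C * H * W
    if flat % caps_dim:
        raise ValueError(
            f"flattened channel size {flat} not divisible by caps_dim {caps_dim}")
    return g.reshape(B, flat // caps_dim, caps_dim)


def predict_capsules(u: Tensor | np.ndarray, W_route: Tensor) -> Tensor:
    """Per-capsule predictions U, shape (..., n, n', d').

    ``W_route`` holds one d×(n'·d') map per input capsule, shape
    (n, d, n', d'); each input capsule predicts every output capsule.
    """
    u = u if isinstance(u, Tensor) else Tensor(u)
    n, d, n_out, d_out = W_route.shape
    w = W_route.reshape(n, d, n_out * d_out)
    if u.ndim == 2:                                        # (n, d)
        out = (u.reshape(n, 1, d) @ w).reshape(n, n_out, d_out)
    else:                                                  # (B, n, d)
        B = u.shape[0]
        out = (u.reshape(B, n, 1, d) @ w.reshape(1, n, d, n_out * d_out))
        out = out.reshape(B, n, n_out, d_out)
    return out


def coupling_coefficients(U: Tensor | np.ndarray, d_l: int) -> Tensor:
    """Self-attention coupling coefficients C of shape (..., n, n').

    Agreement logit for (input i, output j) is the summed inner product of
    U_{ij} with every prediction aimed at j, scaled by sqrt(d_l); the
    softmax runs over the output-capsule axis, so each row of C (fixed
    input capsule) is a distribution over output capsules.
    """
    U = U if isinstance(U, Tensor) else Tensor(U)
    if d_l <= 0:
        raise ValueError("capsule dimension d_l must be positive")
    # gram over input capsules, per output capsule: A[..., j, i, i']
    Ut = U.transpose(*range(U.ndim - 3), U.ndim - 2, U.ndim - 3, U.ndim - 1)
    gram = (Ut @ Ut.transpose(*range(U.ndim - 3), U.ndim - 3,
                              U.ndim - 1, U.ndim - 2)) * (1.0 / np.sqrt(d_l))
    logits = gram.sum(axis=-1)                             # (..., n', n)
    logits = logits.transpose(*range(U.ndim - 3), U.ndim - 2, U.ndim - 3)
    return logits.softmax(axis=-1)                         # softmax over n'


def route(U: Tensor | np.ndarray, C: Tensor | np.ndarray,
          B_prior: Tensor | np.ndarray) -> Tensor:
    """Next-layer capsules s'_j = squash(Σ_i (C_ij + B_ij) · U_{ij}).

    Shapes: U (..., n, n', d'), C and B_prior (..., n, n') (B_prior may be
    unbatched (n, n') and broadcasts).  Returns (..., n', d').
    """
    U = U if isinstance(U, Tensor) else Tensor(U)
    C = C if isinstance(C, Tensor) else Tensor(C)
    B_prior = B_prior if isinstance(B_prior, Tensor) else Tensor(B_prior)
    w = C + B_prior                                        # (..., n, n')
    s = (U * w.reshape(*w.shape, 1)).sum(axis=-3)          # (..., n', d')
    return squash(s)


class CapsuleStage:
    """Primary capsules + one self-attention routing step, batched over patches.

    Geometry: the (C, H, W) feature map from the convolution stack is
    reshaped into ``n = C·H·W / d`` primary capsules of dimension ``d`` and
    routed to ``n_out`` capsules of dimension ``d_out``; the flattened
    output (n_out · d_out) is the per-spot visual feature handed to the
    transformer.
    """

    def __init__(self, c_in: int, h: int, w: int, caps_dim: int = 8,
                 n_out: int = 8, d_out: int = 16, k: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        flat = c_in * h * w
        if flat % caps_dim:
            raise ValueError(
                f"feature size {flat} not divisible by caps_dim {caps_dim}")
        self.n_in = flat // caps_dim
        self.caps_dim, self.n_out, self.d_out = caps_dim, n_out, d_out
        fan = c_in * k * k
        self.conv_w = Tensor(rng.normal(0, np.sqrt(2.0 / fan),
                                        size=(c_in, c_in, k, k)),
                             requires_grad=True)
        self.depth_w = Tensor(rng.normal(0, np.sqrt(1.0 / (k * k)),
                                         size=(c_in, 1, k, k)),
                              requires_grad=True)
        self.W_route = Tensor(rng.normal(0, np.sqrt(1.0 / caps_dim),
                                         size=(self.n_in, caps_dim,
                                               n_out, d_out)),
                              requires_grad=True)
        self.B_prior = Tensor(np.zeros((self.n_in, n_out)), requires_grad=True)

    def parameters(self) -> list:
        return [self.conv_w, self.depth_w, self.W_route, self.B_prior]

    @property
    def out_features(self) -> int:
        return self.n_out * self.d_out

    def __call__(self, feature_map: Tensor) -> Tensor:
        """(B, C, H, W) → (B, n_out · d_out) per-patch capsule features."""
        prim = primary_capsules(feature_map, self.conv_w, self.depth_w,
                                self.caps_dim)
        u = squash(prim)
        U = predict_capsules(u, self.W_route)
        C = coupling_coefficients(U, self.caps_dim)
        out = route(U, C, self.B_prior)
        B = out.shape[0]
        return out.reshape(B, self.n_out * self.d_out)
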