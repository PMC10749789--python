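"""Omni-dimensional dynamic convolution.

A dynamic convolution holds a bank of ``n`` candidate kernels and mixes
them per input sample.  The omni-dimensional variant additionally modulates
the mixed kernel along its spatial (k×k), input-channel and output-channel
axes.  All four attention vectors come from a shared squeeze branch:

    GAP(x) → FC(c_in → r) → ReLU → four head FCs → sigmoid

giving α_w ∈ (0,1)^n, α_k ∈ (0,1)^{k×k}, α_c ∈ (0,1)^{c_in},
α_o ∈ (0,1)^{c_out}.  The effective kernel for a sample is

    W_eff = Σ_i α_wi · (α_k ⊙ α_c ⊙ α_o ⊙ W_i)

broadcast over the remaining kernel axes, followed by an ordinary stride-1
"same" convolution.  With α_k = α_c = α_o ≡ 1 this reduces to plain
dynamic convolution (kernel-wise mixing only), and with n = 1 and all
attentions forced to 1 it is a standard convolution.

The kernel-mixing attention α_w uses a sigmoid by default; a softmax over
the n kernels is available via ``kernel_attention="softmax"`` (the
convention of the original omni-dimensional formulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

__all__ = ["ODAttention", "ODConv", "attention_branch",
           "odconv_forward", "dynamic_conv_forward"]


@dataclass
class ODAttention:
    """The four per-sample attention arrays, each entry in (0, 1)."""

    alpha_w: Tensor   # (B, n)
    alpha_k: Tensor   # (B, k, k)
    alpha_c: Tensor   # (B, c_in)
    alpha_o: Tensor   # (B, c_out)


def _rng_linear(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    scale = np.sqrt(2.0 / n_in)
    return Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                  requires_grad=True)


class ODConv:
    """One omni-dimensional dynamic convolution layer (stride 1, same padding).

    Parameters
    ----------
    c_in, c_out : channel counts.
    k : odd kernel size.
    n : number of candidate kernels.
    reduction : squeeze ratio of the attention branch; the hidden width is
        ``max(c_in // reduction, 8)``.
    kernel_attention : "sigmoid" (default) or "softmax" for α_w.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, n: int = 4,
                 reduction: int = 4, kernel_attention: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("kernel size k must be odd")
        if n < 1:
            raise ValueError("kernel count n must be >= 1")
        if kernel_attention not in ("sigmoid", "softmax"):
            raise ValueError("kernel_attention must be 'sigmoid' or 'softmax'")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.n = c_in, c_out, k, n
        self.kernel_attention = kernel_attention
        r = max(c_in // reduction, 8)
        fan = c_in * k * k
        # He init corrected for the expected attention attenuation: at init
        # every sigmoid head outputs ~0.5, so each kernel is damped by
        # ~0.5^4 and the n-kernel sum scales by sqrt(n); without the gain
        # the effective kernel (and the whole visual pathway) starts ~16x
        # too small and gradients through the image branch vanish.
        gain = 1.0 / (0.5 ** 4 * np.sqrt(n))
        self.kernels = Tensor(
            rng.normal(0.0, gain * np.sqrt(2.0 / fan),
                       size=(n, c_out, c_in, k, k)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        # squeeze FC and the four heads
        self.w_squeeze = _rng_linear(rng, c_in, r)
        self.b_squeeze = Tensor(np.zeros(r), requires_grad=True)
        self.w_heads = {
            "w": _rng_linear(rng, r, n),
            "k": _rng_linear(rng, r, k * k),
            "c": _rng_linear(rng, r, c_in),
            "o": _rng_linear(rng, r, c_out),
        }
        self.b_heads = {key: Tensor(np.zeros(t.shape[1]), requires_grad=True)
                        for key, t in self.w_heads.items()}

    def parameters(self) -> list:
        ps = [self.kernels, self.bias, self.w_squeeze, self.b_squeeze]
        for key in ("w", "k", "c", "o"):
            ps += [self.w_heads[key], self.b_heads[key]]
        return ps

    # ------------------------------------------------------------- attention
    def attention(self, x: Tensor) -> ODAttention:
        """Per-sample attention from (B, c_in, h, w) input."""
        if x.shape[1] != self.c_in:
            raise ValueError(
                f"input has {x.shape[1]} channels, layer expects {self.c_in}")
        B = x.shape[0]
        pooled = x.mean(axis=(2, 3))                       # (B, c_in)
        hidden = (pooled @ self.w_squeeze + self.b_squeeze).relu()
        heads = {key: hidden @ self.w_heads[key] + self.b_heads[key]
                 for key in ("w", "k", "c", "o")}
        if self.kernel_attention == "softmax":
            aw = heads["w"].softmax(axis=-1)
        else:
            aw = heads["w"].sigmoid()
        return ODAttention(
            alpha_w=aw,
            alpha_k=heads["k"].sigmoid().reshape(B, self.k, self.k),
            alpha_c=heads["c"].sigmoid(),
            alpha_o=heads["o"].sigmoid(),
        )

    # --------------------------------------------------------------- forward
    def effective_kernel(self, att: ODAttention) -> Tensor:
        """Per-sample mixed kernel, shape (B, c_out, c_in, k, k)."""
        B = att.alpha_w.shape[0]
        n, c_out, c_in, k = self.n, self.c_out, self.c_in, self.k
        w = self.kernels.reshape(1, n, c_out, c_in, k, k)
        aw = att.alpha_w.reshape(B, n, 1, 1, 1, 1)
        ak = att.alpha_k.reshape(B, 1, 1, 1, k, k)
        ac = att.alpha_c.reshape(B, 1, 1, c_in, 1, 1)
        ao = att.alpha_o.reshape(B, 1, c_out, 1, 1, 1)
        return (aw * ak * ac * ao * w).sum(axis=1)

    def forward(self, x: Tensor, att: ODAttention | None = None,
                omni: bool = True) -> Tensor:
        """Convolve (B, c_in, h, w) → (B, c_out, h, w).

        ``omni=False`` drops the spatial/channel attentions (plain dynamic
        convolution: only α_w mixes the kernel bank).
        """
        x = x if isinstance(x, Tensor) else Tensor(x)
        if att is None:
            att = self.attention(x)
        if not omni:
            ones = Tensor(np.ones(1))
            att = ODAttention(att.alpha_w,
                              alpha_k=Tensor(np.ones((x.shape[0], self.k, self.k))),
                              alpha_c=Tensor(np.ones((x.shape[0], self.c_in))),
                              alpha_o=Tensor(np.ones((x.shape[0], self.c_out))))
            del ones
        w_eff = self.effective_kernel(att)
        out = x.conv2d(w_eff, padding=self.k // 2)
        return out + self.bias.reshape(1, self.c_out, 1, 1)

    __call__ = forward


# Functional surface -----------------------------------------------------

def attention_branch(x, layer: ODConv) -> ODAttention:
    """Attention arrays of ``layer`` for input ``x`` (adds a batch axis to
    a single (c_in, h, w) sample)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    return layer.attention(x)


def odconv_forward(x, layer: ODConv, att: ODAttention | None = None) -> Tensor:
    """Full omni-dimensional forward pass; single samples get a batch axis."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    out = layer.forward(x, att=att, omni=True)
    return out.reshape(*out.shape[1:]) if squeeze else out


def dynamic_conv_forward(x, layer: ODConv,
                         att: ODAttention | None = None) -> Tensor:
    """Kernel-wise mixing only (α_k = α_c = α_o ≡ 1), the ablation mode."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    out = layer.forward(x, att=att, omni=False)
    return out.reshape(*out.shape[1:]) if squeeze else out
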