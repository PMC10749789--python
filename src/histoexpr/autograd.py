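"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its network on CPU with plain numpy; this module supplies
the tensor type, the differentiable operations the architecture needs
(broadcast arithmetic, matmul, convolution, pooling, the usual
nonlinearities, softmax) and an Adam optimizer.  Arrays are float64
throughout: at desk scale the cost is negligible and same-seed runs are
bit-reproducible.

Only what the model uses is implemented; this is not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")
    __array_priority__ = 100  # so ndarray.__mul__ defers to us

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the graph
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return self._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data ** p, (a,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), bw)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return self._make(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), bw)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, a.data, slope * a.data), (a,), bw)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        mask = a.data > 0
        out_data = np.where(mask, a.data, neg)

        def bw(g):
            a._accum(g * np.where(mask, 1.0, neg + alpha))

        return self._make(out_data, (a,), bw)

    def gelu(self):
        # tanh approximation (standard in transformer stacks)
        a = self
        c = np.sqrt(2.0 / np.pi)
        x = a.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dt = (1.0 - t ** 2) * dinner
            a._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return self._make(out_data, (a,), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy()
                         if np.ndim(g) else np.full_like(a.data, g))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.data.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int = -1):
        """Numerically stable softmax; the max shift is treated as constant."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def norm(self, axis=-1, keepdims: bool = False, eps: float = 0.0):
        sq = (self * self).sum(axis=axis, keepdims=keepdims)
        return (sq + eps) ** 0.5 if eps else sq.sqrt()

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._make(a.data[idx], (a,), bw)

    # ------------------------------------------------------------ convolution
    def conv2d(self, weight: "Tensor", padding: int = 0):
        """2-D cross-correlation, stride 1.

        x: (B, Cin, H, W).  weight: (Cout, Cin, k, k) shared across the
        batch, or (B, Cout, Cin, k, k) for a per-sample kernel (dynamic
        convolution computes one effective kernel per patch).
        """
        a, w = self, self._wrap(weight)
        B, Cin, H, W = a.data.shape
        per_sample = w.data.ndim == 5
        Cout, k = (w.data.shape[1], w.data.shape[3]) if per_sample else (
            w.data.shape[0], w.data.shape[2])
        p = padding
        xp = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho, Wo = H + 2 * p - k + 1, W + 2 * p - k + 1
        # im2col: (B, Cin*k*k, Ho*Wo)
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, (B, Cin, k, k, Ho, Wo),
            (s[0], s[1], s[2], s[3], s[2], s[3])).reshape(B, Cin * k * k, -1)
        cols = np.ascontiguousarray(cols)
        wm = w.data.reshape(B, Cout, -1) if per_sample else w.data.reshape(Cout, -1)
        out_data = np.matmul(wm, cols).reshape(B, Cout, Ho, Wo)

        def bw(g):
            gm = g.reshape(B, Cout, -1)
            if w.requires_grad:
                gw = np.matmul(gm, cols.transpose(0, 2, 1))
                if per_sample:
                    w._accum(gw.reshape(w.data.shape))
                else:
                    w._accum(gw.sum(axis=0).reshape(w.data.shape))
            if a.requires_grad:
                if per_sample:
                    gcols = np.matmul(wm.transpose(0, 2, 1), gm)
                else:
                    gcols = np.matmul(wm.T, gm)
                gxp = np.zeros_like(xp)
                gc = gcols.reshape(B, Cin, k, k, Ho, Wo)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di:di + Ho, dj:dj + Wo] += gc[:, :, di, dj]
                a._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        return self._make(out_data, (a, w), bw)

    def avg_pool2d(self, k: int):
        """Non-overlapping k×k average pooling on (B, C, H, W); H, W divisible by k."""
        a = self
        B, C, H, W = a.data.shape
        if H % k or W % k:
            raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {k}")
        out_data = a.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

        def bw(g):
            gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            a._accum(gg)

        return self._make(out_data, (a,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)


class Adam:
    """Adam with the standard bias correction; deterministic given ordering."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
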