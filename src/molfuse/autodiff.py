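"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every :class:`Tensor` records the
operation that produced it and closes over the local gradient rule. Calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates ``grad`` on every tensor with
``requires_grad=True``.

Only the operations the molecular models need are provided: broadcasting
arithmetic, matmul, reductions, reshaping/slicing, the usual nonlinearities,
and stride-1 2-D convolution (via im2col) with average-pool and
nearest-neighbour upsampling expressed as composites. Convolution input
gradients are computed as a transposed convolution with flipped kernels
rather than a scatter-add, which keeps the backward pass BLAS-bound.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv2d", "avg_pool2d", "upsample2x", "no_grad"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (forward-only compute)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype) if dtype is not None else np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other, like=None):
        if isinstance(other, Tensor):
            return other
        if like is not None and isinstance(other, (int, float)):
            # keep python scalars at the partner's dtype (no f32->f64 creep)
            return Tensor(np.asarray(other, dtype=like))
        return Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- introspection --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other, self.data.dtype)
        data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other, self.data.dtype))

    def __rsub__(self, other):
        return self._wrap(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = self._wrap(other, self.data.dtype)
        data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other, self.data.dtype)
        data = self.data / other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other, self.data.dtype) / self

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other, self.data.dtype)
        data = np.matmul(self.data, other.data)

        def backward(g, a=self, b=other):
            ad, bd = a.data, b.data
            # promote 1-D operands to matrices (matching np.matmul semantics)
            a2 = ad.reshape(1, -1) if ad.ndim == 1 else ad
            b2 = bd.reshape(-1, 1) if bd.ndim == 1 else bd
            g2 = g
            if ad.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if bd.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            if a.requires_grad:
                ga = np.matmul(g2, np.swapaxes(b2, -1, -2))
                if ad.ndim == 1:
                    ga = ga.reshape(-1, ad.shape[0]).sum(axis=0) if ga.ndim > 2 else ga.reshape(ad.shape)
                a._accum(_unbroadcast(ga, ad.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a2, -1, -2), g2)
                if bd.ndim == 1:
                    gb = gb.reshape(-1, bd.shape[0]).sum(axis=0) if gb.ndim > 2 else gb.reshape(bd.shape)
                b._accum(_unbroadcast(gb, bd.shape))

        return self._make(data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def backward(g, a=self, d=data):
            if a.requires_grad:
                a._accum(g * d)

        return self._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(data, (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g, a=self, d=data):
            if a.requires_grad:
                a._accum(g * 0.5 / d)

        return self._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(data, (self,), backward)

    def sigmoid(self):
        data = np.empty_like(self.data)
        pos = self.data >= 0
        data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        data[~pos] = ex / (1.0 + ex)

        def backward(g, a=self, d=data):
            if a.requires_grad:
                a._accum(g * d * (1.0 - d))

        return self._make(data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only inside the interval."""
        mask = (self.data > lo) & (self.data < hi)
        data = np.clip(self.data, lo, hi)

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not kd:
                axes = ax if isinstance(ax, tuple) else (ax,)
                axes = tuple(x % a.data.ndim for x in axes)
                g = np.expand_dims(g, axis=tuple(sorted(axes)))
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[x] for x in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax (max-subtraction, shift detached)."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return self._make(data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return self._make(data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        # walk the tape in reverse, releasing each node's gradient and its
        # links as soon as it has been consumed so peak memory stays close to
        # the forward pass (important for the image network's large maps)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                if t is not self:
                    t.grad = None  # interior node: gradient fully consumed
                t._parents = ()
                t._backward = None


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always True)."""

    def __init__(self, data, dtype=None):
        super().__init__(np.array(data, dtype=dtype, copy=True), requires_grad=True)

    def zero_grad(self):
        self.grad = None


# -- free functions -----------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out._parents = tuple(tensors)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(B,C,H,W) -> (B*H_out*W_out, C*kh*kw) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (B, C, ho, wo, kh, kw) -> (B, ho, wo, C, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _conv_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation on raw arrays. w: (F,C,kh,kw)."""
    f, c, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, pad)
    out = cols @ w.reshape(f, -1).T
    return out.reshape(x.shape[0], ho, wo, f).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution. x: (B,C,H,W); w: (F,C,kh,kw); b: (F,).

    The input gradient is computed as a stride-1 convolution of the output
    gradient with channel-swapped, spatially flipped kernels (valid for any
    kernel size with ``full_pad = k - 1 - pad``).
    """
    x, w = Tensor._wrap(x), Tensor._wrap(w)
    f, c, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, pad)
    out_mat = cols @ w.data.reshape(f, -1).T
    data = out_mat.reshape(x.data.shape[0], ho, wo, f).transpose(0, 3, 1, 2)
    if b is not None:
        data = data + b.data.reshape(1, f, 1, 1)
    out = Tensor(data)
    parents = (x, w) if b is None else (x, w, b)
    out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if out.requires_grad:

        def backward(g):
            g_mat = g.transpose(0, 2, 3, 1).reshape(-1, f)  # (B*ho*wo, F)
            if w.requires_grad:
                gw = (cols.T @ g_mat).T.reshape(w.data.shape)
                w._accum(gw)
            if b is not None and b.requires_grad:
                b._accum(g_mat.sum(axis=0))
            if x.requires_grad:
                w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,kh,kw)
                gx = _conv_raw(g, np.ascontiguousarray(w_flip), kh - 1 - pad)
                x._accum(gx)

        out._parents = parents
        out._backward = backward
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k average pooling (composite op)."""
    b, c, h, w = x.shape
    y = x.reshape(b, c, h // k, k, w // k, k).sum(axis=(3, 5))
    return y * (1.0 / (k * k))

def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling (composite op)."""
    b, c, h, w = x.shape
    ones = Tensor(np.ones((1, 1, 1, 2, 1, 2), dtype=x.data.dtype))
    y = x.reshape(b, c, h, 1, w, 1) * ones
    return y.reshape(b, c, 2 * h, 2 * w)
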