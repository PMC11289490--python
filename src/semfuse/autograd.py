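"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the differentiable operations the
fusion, segmentation and loss modules need: elementwise arithmetic with
broadcasting, reductions, slicing/concatenation, reflective padding, strided
2-D convolution (im2col), bilinear upsampling and the activation functions.
Arrays are float64 throughout so that finite-difference gradient checks are
meaningful.

Typical use::

    x = Tensor(np.random.rand(1, 3, 8, 8), requires_grad=True)
    y = (x * 2.0 + 1.0).sum()
    y.backward()
    x.grad  # -> dy/dx
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "maximum", "conv2d",
           "pad_reflect", "upsample_bilinear", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    """Context manager disabling graph construction (forward-only passes)."""

    _enabled = True  # graph construction enabled

    def __enter__(self):
        self._prev = _NoGrad._enabled
        _NoGrad._enabled = False
        return self

    def __exit__(self, *exc):
        _NoGrad._enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _NoGrad._enabled
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the tape
        for node in topo:
            node._parents = ()
            node._backward = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------ operators
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b.data, lambda g, a, b: g * a.data)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return _unary(self, lambda a: -a, lambda g, a, out: -g)

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b.data,
                       lambda g, a, b: -g * a.data / (b.data ** 2))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return _unary(self, lambda a: a ** e,
                      lambda g, a, out: g * e * a.data ** (e - 1.0))

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)
            src_shape = self.data.shape

            def bw(g, self=self, idx=idx, src_shape=src_shape):
                # only basic (slice/int/Ellipsis) indexing is used in-package,
                # so indexed positions never alias and += is safe
                full = np.zeros(src_shape, dtype=np.float64)
                full[idx] += g
                self._accumulate(full)

            out._backward = bw
        return out

    # ------------------------------------------------------------ functions
    def exp(self):
        return _unary(self, np.exp, lambda g, a, out: g * out.data)

    def log(self):
        return _unary(self, np.log, lambda g, a, out: g / a.data)

    def sqrt(self):
        return _unary(self, np.sqrt, lambda g, a, out: g * 0.5 / out.data)

    def abs(self):
        return _unary(self, np.abs, lambda g, a, out: g * np.sign(a.data))

    def clip(self, lo: float, hi: float):
        return _unary(self, lambda a: np.clip(a, lo, hi),
                      lambda g, a, out: g * ((a.data >= lo) & (a.data <= hi)))

    def sigmoid(self):
        def fwd(a):
            out = np.empty_like(a)
            pos = a >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
            ea = np.exp(a[~pos])
            out[~pos] = ea / (1.0 + ea)
            return out

        return _unary(self, fwd,
                      lambda g, a, out: g * out.data * (1.0 - out.data))

    def relu(self):
        return _unary(self, lambda a: np.maximum(a, 0.0),
                      lambda g, a, out: g * (a.data > 0))

    def leaky_relu(self, slope: float = 0.01):
        return _unary(self, lambda a: np.where(a > 0, a, slope * a),
                      lambda g, a, out: g * np.where(a.data > 0, 1.0, slope))

    def hswish(self):
        """x * relu6(x + 3) / 6 (hard swish)."""
        return self * (self + 3.0).clip(0.0, 6.0) * (1.0 / 6.0)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)
            shape = self.data.shape

            def bw(g, self=self, axis=axis, keepdims=keepdims, shape=shape):
                if axis is None:
                    full = np.broadcast_to(g, shape)
                else:
                    if not keepdims:
                        ax = axis if isinstance(axis, tuple) else (axis,)
                        ax = tuple(a % len(shape) for a in ax)
                        g = np.expand_dims(g, ax)
                    full = np.broadcast_to(g, shape)
                self._accumulate(np.ascontiguousarray(full))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data)
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)

            def bw(g, self=self, axis=axis, keepdims=keepdims, out_data=out_data):
                od, gg = out_data, g
                if axis is not None and not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    ax = tuple(a % self.data.ndim for a in ax)
                    od = np.expand_dims(od, ax)
                    gg = np.expand_dims(gg, ax)
                mask = (self.data == od)
                counts = mask.sum(axis=axis, keepdims=True) if axis is not None \
                    else mask.sum()
                self._accumulate(mask * (gg / counts))

            out._backward = bw
        return out

    # -------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)
            src = self.data.shape
            out._backward = lambda g, self=self, src=src: \
                self._accumulate(g.reshape(src))
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        out = Tensor(self.data.transpose(axes))
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)
            inv = tuple(np.argsort(axes))
            out._backward = lambda g, self=self, inv=inv: \
                self._accumulate(g.transpose(inv))
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis))
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g, self=self, axis=axis: \
                self._accumulate(np.flip(g, axis=axis))
        return out

    def repeat(self, k: int, axis: int):
        """Nearest-neighbour upscaling along one axis (each element k times)."""
        out = Tensor(np.repeat(self.data, k, axis=axis))
        if self.requires_grad and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self,)
            nd = self.data.ndim
            shape = self.data.shape

            def bw(g, self=self, k=k, axis=axis, nd=nd, shape=shape):
                ax = axis % nd
                new_shape = shape[:ax] + (shape[ax], k) + shape[ax + 1:]
                self._accumulate(g.reshape(new_shape).sum(axis=ax + 1))

            out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data)
        if (self.requires_grad or other.requires_grad) and _NoGrad._enabled:
            out.requires_grad = True
            out._parents = (self, other)

            def bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accumulate(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accumulate(_unbroadcast(gb, b.data.shape))

            out._backward = bw
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(a: Tensor, fwd, bwd) -> Tensor:
    out = Tensor(fwd(a.data))
    if a.requires_grad and _NoGrad._enabled:
        out.requires_grad = True
        out._parents = (a,)
        out._backward = lambda g, a=a, out=out: a._accumulate(bwd(g, a, out))
    return out


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data))
    if (a.requires_grad or b.requires_grad) and _NoGrad._enabled:
        out.requires_grad = True
        out._parents = (a, b)

        def bw(g, a=a, b=b):
            if a.requires_grad:
                a._accumulate(_unbroadcast(bwd_a(g, a, b), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(bwd_b(g, a, b), b.data.shape))

        out._backward = bw
    return out


def maximum(a, b) -> Tensor:
    """Elementwise max; ties split the gradient equally."""

    def bwd_a(g, a, b):
        return g * np.where(a.data > b.data, 1.0,
                            np.where(a.data == b.data, 0.5, 0.0))

    def bwd_b(g, a, b):
        return g * np.where(b.data > a.data, 1.0,
                            np.where(a.data == b.data, 0.5, 0.0))

    return _binary(a, b, np.maximum, bwd_a, bwd_b)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis))
    if _NoGrad._enabled and any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)
        sizes = [t.data.shape[axis] for t in ts]

        def bw(g, ts=ts, sizes=sizes, axis=axis):
            start = 0
            for t, s in zip(ts, sizes):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(start, start + s)
                    t._accumulate(g[tuple(sl)])
                start += s

        out._backward = bw
    return out


# ---------------------------------------------------------------- padding
def _reflect_index(n: int, p: int) -> np.ndarray:
    """Indices implementing numpy 'reflect' padding of width p along length n."""
    idx = np.arange(-p, n + p)
    period = 2 * n - 2 if n > 1 else 1
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def pad_reflect(x: Tensor, p: int) -> Tensor:
    """Reflective padding of the last two (spatial) axes by p pixels."""
    if p == 0:
        return x
    h, w = x.shape[-2], x.shape[-1]
    ih = _reflect_index(h, p)
    iw = _reflect_index(w, p)
    out = Tensor(x.data[..., ih[:, None], iw[None, :]])
    if x.requires_grad and _NoGrad._enabled:
        out.requires_grad = True
        out._parents = (x,)

        def bw(g, x=x, ih=ih, iw=iw):
            full = np.zeros(x.data.shape, dtype=np.float64)
            np.add.at(full, (Ellipsis, ih[:, None], iw[None, :]), g)
            x._accumulate(full)

        out._backward = bw
    return out


# ------------------------------------------------------------- convolution
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, reflective padding.

    x: (N, C, H, W); w: (O, C, k, k); b: (O,) or None.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    if padding:
        x = pad_reflect(x, padding)
    n, c, h, ww_ = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    if h < kh or ww_ < kw:
        raise ValueError("conv2d: spatial size smaller than kernel")
    s = stride
    ho = (h - kh) // s + 1
    wo = (ww_ - kw) // s + 1

    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw),
                                                       axis=(2, 3))
    windows = windows[:, :, ::s, ::s, :, :]          # N,C,Ho,Wo,kh,kw
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out_data = cols @ wmat.T                          # N, Ho*Wo, O
    out_data = out_data.transpose(0, 2, 1).reshape(n, o, ho, wo)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, o, 1, 1)

    out = Tensor(out_data)
    parents = [t for t in (x, w, b) if t is not None and t.requires_grad]
    if parents and _NoGrad._enabled:
        out.requires_grad = True
        out._parents = tuple(parents)

        def bw(g, x=x, w=w, b=b, cols=cols, wmat=wmat,
               n=n, c=c, kh=kh, kw=kw, ho=ho, wo=wo, s=s):
            gmat = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, w.data.shape[0])
            if w.requires_grad:
                dw = np.einsum("nlo,nlk->ok", gmat, cols)
                w._accumulate(dw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = gmat @ wmat                    # N, Ho*Wo, C*kh*kw
                dcols = dcols.reshape(n, ho, wo, c, kh, kw)
                dx = np.zeros(x.data.shape, dtype=np.float64)
                for i in range(kh):
                    for j in range(kw):
                        dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                x._accumulate(dx)

        out._backward = bw
    return out


# ------------------------------------------------------------- upsampling
def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m


def upsample_bilinear(x: Tensor, factor: int = 2) -> Tensor:
    """Bilinear upsampling of the last two axes by an integer factor."""
    h, w = x.shape[-2], x.shape[-1]
    ah = _bilinear_matrix(h, h * factor)
    aw = _bilinear_matrix(w, w * factor)
    out_data = np.einsum("ph,...hw,qw->...pq", ah, x.data, aw, optimize=True)
    out = Tensor(out_data)
    if x.requires_grad and _NoGrad._enabled:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = lambda g, x=x, ah=ah, aw=aw: x._accumulate(
            np.einsum("ph,...pq,qw->...hw", ah, g, aw, optimize=True))
    return out
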