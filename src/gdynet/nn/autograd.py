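"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd style: every :class:`Tensor`
records the operation that produced it and a closure that propagates the
upstream gradient to its parents.  ``backward()`` runs a topological sort
and accumulates gradients into every node that requires them, which is
exactly what class-activation-map construction needs (per-layer activation
gradients are first-class citizens here, not an afterthought).

Data is float32 by default (the training loops are memory-bound on CPU);
``default_dtype(np.float64)`` switches the engine to double precision,
which keeps central finite differences an honest oracle when checking
the analytic gradients.

Array layout is NCHW throughout (batch, channels, height, width).
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "default_dtype", "get_default_dtype",
           "set_default_dtype"]

# float32 keeps the CNN training loops memory-bound workloads fast on a
# CPU; switch to float64 (e.g. for finite-difference gradient checks)
# via set_default_dtype / the default_dtype context manager.
_DEFAULT_DTYPE = np.float32


def get_default_dtype():
    return _DEFAULT_DTYPE


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype.type


@contextmanager
def default_dtype(dtype):
    """Temporarily switch the engine's floating-point precision."""
    prev = get_default_dtype()
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ---------------------------------------------------

    @classmethod
    def _from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; accumulates into ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad,
                               dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        return self * (other ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) * (self ** -1.0)

    def __pow__(self, exponent: float) -> "Tensor":
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._from_op(out_data, (a,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._from_op(a.data @ b.data, (a, b), backward)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.shape

        def backward(g):
            a._accum(g.reshape(orig))

        return Tensor._from_op(a.data.reshape(shape), (a,), backward)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

        return Tensor._from_op(a.data[idx], (a,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).astype(a.data.dtype))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(x % a.ndim for x in ax)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.shape).astype(a.data.dtype))

        return Tensor._from_op(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[x % self.ndim] for x in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        """ReLU with a small negative slope (avoids dead units in the
        normalization-free segmentation net)."""
        a = self
        mask = a.data > 0
        scale = np.where(mask, 1.0, slope).astype(a.data.dtype)

        def backward(g):
            a._accum(g * scale)

        return Tensor._from_op(a.data * scale, (a,), backward)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def backward(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(np.clip(a.data, -700, 700))

        def backward(g):
            a._accum(g * e)

        return Tensor._from_op(e, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where unclipped."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            a._accum(g * mask)

        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), backward)

    # -- convolution and pooling -----------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1) -> "Tensor":
        """2-d cross-correlation, NCHW, via im2col + batched matmul.

        ``weight`` has shape (C_out, C_in // groups, kh, kw).  Grouped
        convolution implements the split-transform-merge branches of a
        ResNeXt block without a Python-level loop over the cardinality.
        """
        x, w = self, weight
        n, c_in, h, w_in = x.shape
        c_out, c_in_g, kh, kw = w.shape
        if c_in % groups or c_out % groups or c_in // groups != c_in_g:
            raise ValueError(
                f"channels ({c_in}->{c_out}) incompatible with groups={groups}")
        s = stride
        xp = (np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2,
                              (padding,) * 2)) if padding else x.data)
        h_out = (h + 2 * padding - kh) // s + 1
        w_out = (w_in + 2 * padding - kw) // s + 1
        # windows: (N, C, H_out, W_out, kh, kw)
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        cg = c_out // groups
        # cols: (N, G, H_out*W_out, C_in_g*kh*kw)
        cols = (win.reshape(n, groups, c_in_g, h_out, w_out, kh * kw)
                   .transpose(0, 1, 3, 4, 2, 5)
                   .reshape(n, groups, h_out * w_out, c_in_g * kh * kw))
        wg = w.data.reshape(groups, cg, c_in_g * kh * kw)
        out = np.matmul(cols, wg.transpose(0, 2, 1))  # (N, G, HW, cg)
        out = (out.transpose(0, 1, 3, 2)
                  .reshape(n, c_out, h_out, w_out))
        if bias is not None:
            out = out + bias.data.reshape(1, c_out, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            gout = (g.reshape(n, groups, cg, h_out * w_out)
                     .transpose(0, 1, 3, 2))          # (N, G, HW, cg)
            if w.requires_grad:
                gw = np.einsum("ngpo,ngpk->gok", gout, cols)
                w._accum(gw.reshape(c_out, c_in_g, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.matmul(gout, wg)           # (N, G, HW, K)
                gcols = (gcols.reshape(n, groups, h_out, w_out, c_in_g, kh, kw)
                              .transpose(0, 1, 4, 5, 6, 2, 3)
                              .reshape(n, c_in, kh, kw, h_out, w_out))
                gxp = np.zeros_like(xp)
                for ih in range(kh):
                    for iw in range(kw):
                        gxp[:, :, ih:ih + s * h_out:s,
                            iw:iw + s * w_out:s] += gcols[:, :, ih, iw]
                if padding:
                    gxp = gxp[:, :, padding:-padding or None,
                              padding:-padding or None]
                x._accum(gxp)

        return Tensor._from_op(out, parents, backward)

    def max_pool2d(self, k: int = 2) -> "Tensor":
        """k x k max pooling with stride k (spatial dims must divide)."""
        a = self
        n, c, h, w = a.shape
        if h % k or w % k:
            raise ValueError(f"spatial size {(h, w)} not divisible by {k}")
        win = a.data.reshape(n, c, h // k, k, w // k, k)
        flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
            ga = (gflat.reshape(n, c, h // k, w // k, k, k)
                       .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))
            a._accum(ga)

        return Tensor._from_op(out, (a,), backward)

    def max_pool2d_same(self, k: int = 3) -> "Tensor":
        """k x k max pooling with stride 1 and same padding (odd k).

        Computed by k*k shifted comparisons instead of materializing
        windows; gradient routes to the first window position attaining
        the maximum (argmax tie-break).
        """
        a = self
        n, c, h, w = a.shape
        p = k // 2
        xp = np.pad(a.data, ((0, 0), (0, 0), (p,) * 2, (p,) * 2),
                    constant_values=-np.inf)
        out = np.full((n, c, h, w), -np.inf)
        arg = np.zeros((n, c, h, w), dtype=np.int8)
        for j, (dr, dc) in enumerate((dr, dc) for dr in range(k)
                                     for dc in range(k)):
            v = xp[:, :, dr:dr + h, dc:dc + w]
            better = v > out
            np.copyto(out, v, where=better)
            np.copyto(arg, np.int8(j), where=better)

        def backward(g):
            gxp = np.zeros_like(xp)
            for j, (dr, dc) in enumerate((dr, dc) for dr in range(k)
                                         for dc in range(k)):
                sel = arg == j
                if sel.any():
                    gxp[:, :, dr:dr + h, dc:dc + w] += np.where(sel, g, 0.0)
            a._accum(gxp[:, :, p:p + h, p:p + w])

        return Tensor._from_op(out, (a,), backward)

    def avg_pool2d(self, k: int = 2) -> "Tensor":
        a = self
        n, c, h, w = a.shape
        if h % k or w % k:
            raise ValueError(f"spatial size {(h, w)} not divisible by {k}")
        out = a.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

        def backward(g):
            ga = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            a._accum(ga)

        return Tensor._from_op(out, (a,), backward)

    def global_avg_pool(self) -> "Tensor":
        """Mean over spatial dims: (N, C, H, W) -> (N, C)."""
        return self.mean(axis=(2, 3))

    def upsample_bilinear(self, size: tuple[int, int]) -> "Tensor":
        """Bilinear resize to ``size`` (align-corners mapping).

        Realized as y = R x C^T per (batch, channel); the backward pass is
        the exact transpose of the same linear map.
        """
        a = self
        n, c, h, w = a.shape
        ho, wo = size
        rw = _interp_matrix(h, ho).astype(a.data.dtype)
        cw = _interp_matrix(w, wo).astype(a.data.dtype)
        out = np.einsum("oh,nchw,pw->ncop", rw, a.data, cw, optimize=True)

        def backward(g):
            ga = np.einsum("oh,ncop,pw->nchw", rw, g, cw, optimize=True)
            a._accum(ga)

        return Tensor._from_op(out, (a,), backward)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-interpolation matrix (n_out x n_in), align-corners bilinear."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = (np.arange(n_out) * (n_in - 1) / max(n_out - 1, 1)
           if n_out > 1 else np.array([0.0]))
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    ts = list(tensors)
    if not ts:
        raise ValueError("concat of an empty sequence")
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o, s in zip(ts, offsets[:-1], sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + s)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(np.concatenate([t.data for t in ts], axis=axis),
                           ts, backward)
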