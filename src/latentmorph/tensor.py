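"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The style-based generator, its discriminator, and the latent-code projection
loop all need gradients (the R1 penalty even needs a gradient of a gradient
norm, i.e. double backward). This module provides the small operator set those
models require: elementwise arithmetic, reductions, matmul, im2col/col2im based
convolution plumbing, 2x resampling, rolls, concatenation and slicing.

Cotangents are themselves ``Tensor`` objects and every vector-Jacobian product
is expressed through the same primitives, so ``grad(..., create_graph=True)``
yields a differentiable graph and second-order terms come out correctly
(activation masks are treated as locally constant, which is exact almost
everywhere for piecewise-linear nonlinearities).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "leaky_relu",
    "softplus",
    "im2col",
    "col2im",
    "upsample2x",
    "sumpool2x",
    "roll",
    "flip",
    "concat",
    "narrow",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus the backward edges that produced it."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._parents: list[tuple["Tensor", Callable]] = []

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def tensor(data, requires_grad: bool = False, dtype=None) -> Tensor:
    arr = np.asarray(data, dtype=dtype)
    return Tensor(arr, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Iterable[tuple[Tensor, Callable]]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        tracked = [(p, fn) for p, fn in parents if p.requires_grad]
        if tracked:
            out.requires_grad = True
            out._parents = tracked
    return out


def _sum_to(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a broadcast cotangent back to ``shape``."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# -- elementwise arithmetic ----------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data + b.data, [(a, lambda g: _sum_to(g, a.shape)),
                                   (b, lambda g: _sum_to(g, b.shape))])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data - b.data, [(a, lambda g: _sum_to(g, a.shape)),
                                   (b, lambda g: _sum_to(neg(g), b.shape))])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data * b.data, [(a, lambda g: _sum_to(mul(g, b), a.shape)),
                                   (b, lambda g: _sum_to(mul(g, a), b.shape))])


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, power(b, -1.0))


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, [(a, lambda g: neg(g))])


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _make(a.data ** p, [(a, lambda g: mul(g, mul(Tensor(np.asarray(p, dtype=a.dtype)),
                                                        power(a, p - 1.0))))])


def square(a: Tensor) -> Tensor:
    return mul(a, a)


def exp(a: Tensor) -> Tensor:
    holder: list[Tensor] = []
    out = _make(np.exp(a.data), [(a, lambda g: mul(g, holder[0]))])
    holder.append(out)
    return out


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def sigmoid(a: Tensor) -> Tensor:
    one = Tensor(np.asarray(1.0, dtype=a.dtype))
    return div(one, add(one, exp(neg(a))))


def softplus(a: Tensor) -> Tensor:
    # log(1 + e^x), computed stably; d/dx = sigmoid(x)
    data = np.logaddexp(np.zeros((), dtype=a.dtype), a.data)
    return _make(data, [(a, lambda g: mul(g, sigmoid(a)))])


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = (a.data > 0).astype(a.dtype)
    scale = mask + slope * (1.0 - mask)
    return _make(a.data * scale, [(a, lambda g: mul(g, Tensor(scale)))])


# -- reductions / shape --------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        gd = g
        if axis is not None and not keepdims:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            shape = list(a.shape)
            for i in sorted(a2 % a.ndim for a2 in ax):
                shape[i] = 1
            gd = reshape(gd, tuple(shape))
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * a.ndim)
        return broadcast_to(gd, a.shape)

    return _make(data, [(a, vjp)])


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def broadcast_to(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    return _make(np.broadcast_to(a.data, shape).copy(), [(a, lambda g: _sum_to(g, a.shape))])


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def swap_last(t: Tensor) -> Tensor:
        perm = list(range(t.ndim))
        perm[-1], perm[-2] = perm[-2], perm[-1]
        return transpose(t, perm)

    return _make(data, [
        (a, lambda g: _sum_to(matmul(g, swap_last(b)), a.shape)),
        (b, lambda g: _sum_to(matmul(swap_last(a), g), b.shape)),
    ])


# -- structural ops ------------------------------------------------------------

def roll(a: Tensor, shift: int, axis: int) -> Tensor:
    return _make(np.roll(a.data, shift, axis=axis),
                 [(a, lambda g: roll(g, -shift, axis))])


def flip(a: Tensor, axis: int) -> Tensor:
    return _make(np.flip(a.data, axis=axis).copy(), [(a, lambda g: flip(g, axis))])


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        length = t.shape[axis]
        parents.append((t, (lambda s, l: lambda g: narrow(g, axis, s, l))(start, length)))
        start += length
    return _make(data, parents)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    total = a.shape[axis]
    return _make(a.data[tuple(sl)].copy(),
                 [(a, lambda g: pad_insert(g, axis, start, total))])


def pad_insert(a: Tensor, axis: int, start: int, total: int) -> Tensor:
    """Embed ``a`` into a zero array of ``total`` extent along ``axis``."""
    shape = list(a.shape)
    length = shape[axis]
    shape[axis] = total
    data = np.zeros(shape, dtype=a.dtype)
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    data[tuple(sl)] = a.data
    return _make(data, [(a, lambda g: narrow(g, axis, start, length))])


# -- convolution plumbing ------------------------------------------------------

def im2col(a: Tensor, k: int) -> Tensor:
    """(B,C,H,W) -> (B, C*k*k, H*W) sliding windows, stride 1, zero 'same' pad."""
    B, C, H, W = a.shape
    p = k // 2
    padded = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, C, k, k, H, W)
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(B, C * k * k, H * W)
    return _make(cols, [(a, lambda g: col2im(g, (C, H, W), k))])


def col2im(cols: Tensor, chw: tuple[int, int, int], k: int) -> Tensor:
    """Adjoint of :func:`im2col`: scatter-add windows back to (B,C,H,W)."""
    C, H, W = chw
    B = cols.shape[0]
    p = k // 2
    blocks = cols.data.reshape(B, C, k, k, H, W)
    padded = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            padded[:, :, i:i + H, j:j + W] += blocks[:, :, i, j]
    out = padded[:, :, p:p + H, p:p + W]
    return _make(out, [(cols, lambda g: im2col(g, k))])


def _blur3_data(a: np.ndarray) -> np.ndarray:
    out = a
    for axis in (-2, -1):
        out = 0.25 * (np.roll(out, 1, axis) + 2.0 * out + np.roll(out, -1, axis))
    return out.astype(a.dtype, copy=False)


def blur3(a: Tensor) -> Tensor:
    """Separable binomial [1,2,1]/4 blur with circular boundary; self-adjoint."""
    return _make(_blur3_data(a.data), [(a, lambda g: blur3(g))])


def upsample2x(a: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (B,C,H,W)."""
    data = a.data.repeat(2, axis=-2).repeat(2, axis=-1)
    return _make(data, [(a, lambda g: sumpool2x(g))])


def sumpool2x(a: Tensor) -> Tensor:
    """2x2 block sum of (B,C,H,W); adjoint of nearest upsampling."""
    B, C, H, W = a.shape
    data = a.data.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
    return _make(data, [(a, lambda g: upsample2x(g))])


# -- backward ------------------------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if parent.requires_grad and id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(output: Tensor, inputs: Sequence[Tensor], grad_output: Tensor | None = None,
         create_graph: bool = False) -> list[Tensor]:
    """Cotangents of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own backward
    graph, enabling higher-order derivatives.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape, dtype=output.dtype))

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        order = _toposort(output)
        grads: dict[int, Tensor] = {id(output): grad_output}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else add(acc, pg)
            # keep inputs' grads retrievable
            if node in inputs:
                grads[id(node)] = g
        out = []
        for t in inputs:
            g = grads.get(id(t))
            if g is None:
                g = Tensor(np.zeros(t.shape, dtype=t.dtype))
            out.append(g)
    return out
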