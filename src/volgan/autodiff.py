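"""Reverse-mode automatic differentiation on numpy arrays.

Small tape-based engine powering the volumetric GAN stack.  Every vector-Jacobian
product (VJP) is itself expressed through the same differentiable primitives, so
gradients of gradients work to arbitrary order — the property required by the
two-sided gradient penalty, whose critic update differentiates through
``grad(critic(x), x)``.

Only the primitives the networks need are implemented: elementwise arithmetic,
matmul, reductions, shape ops, leaky ReLU, 3D convolution (with the adjoint
input-gradient / weight-gradient pair forming a closed family), nearest-neighbour
upsampling and its block-sum adjoint.  Convolutions are evaluated as 27 shifted
``tensordot`` contractions rather than one big im2col matmul to bound peak memory.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "add", "sub", "mul", "div", "neg", "power", "matmul",
    "tsum", "tmean", "reshape", "transpose", "broadcast_to",
    "exp", "log", "sqrt", "clip", "leaky_relu",
    "conv3d", "upsample2", "blocksum2", "flip_spatial",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape edges needed for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "_edges")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._edges: tuple = ()

    # -- conveniences -------------------------------------------------------
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
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _pair(a, b) -> tuple:
    """Lift operands to tensors; a bare python scalar adopts the other
    operand's float dtype so float32 networks stay float32."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.isscalar(b):
        return a, Tensor(np.asarray(b, dtype=a.dtype))
    if isinstance(b, Tensor) and not isinstance(a, Tensor) and np.isscalar(a):
        return Tensor(np.asarray(a, dtype=b.dtype)), b
    return as_tensor(a), as_tensor(b)


def _make(data: np.ndarray, edges: Iterable[tuple]) -> Tensor:
    """Build a result tensor; record tape edges only for grad-requiring parents."""
    kept = tuple((p, fn) for p, fn in edges if p.requires_grad)
    out = Tensor(data, requires_grad=bool(kept) and _GRAD_ENABLED)
    if out.requires_grad:
        out._edges = kept
    return out


# ---------------------------------------------------------------------------
# broadcasting helper: reduce g down to `shape`
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    keep = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if keep:
        g = tsum(g, axis=keep, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _pair(a, b)
    return _make(a.data + b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ])


def sub(a, b) -> Tensor:
    a, b = _pair(a, b)
    return _make(a.data - b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(neg(g), b.shape)),
    ])


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a, b) -> Tensor:
    a, b = _pair(a, b)
    return _make(a.data * b.data, [
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ])


def div(a, b) -> Tensor:
    a, b = _pair(a, b)
    return _make(a.data / b.data, [
        (a, lambda g: _unbroadcast(div(g, b), a.shape)),
        (b, lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)),
    ])


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return _make(a.data ** p, [(a, lambda g: mul(g, mul(p, power(a, p - 1.0))))])


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.exp(a.data), [(a, lambda g: mul(g, out))])
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.sqrt(a.data), [(a, lambda g: div(g, mul(2.0, out)))])
    return out


def clip(a, lo=None, hi=None) -> Tensor:
    """Clamp; the pass-through mask is treated as locally constant."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask = mask * (a.data >= lo)
    if hi is not None:
        mask = mask * (a.data <= hi)
    return _make(data, [(a, lambda g: mul(g, Tensor(mask)))])


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return _make(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if not keepdims:
            shp = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = reshape(g, shp)
        return broadcast_to(g, a.shape)

    return _make(data, [(a, vjp)])


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(np.broadcast_to(a.data, shape).copy(),
                 [(a, lambda g: _unbroadcast(g, a.shape))])


def matmul(a, b) -> Tensor:
    """2D (or stacked) matrix product with transpose-based VJPs."""
    a, b = as_tensor(a), as_tensor(b)

    def _T(t):
        order = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
        return transpose(t, order)

    return _make(a.data @ b.data, [
        (a, lambda g: _unbroadcast(matmul(g, _T(b)), a.shape)),
        (b, lambda g: _unbroadcast(matmul(_T(a), g), b.shape)),
    ])


def flip_spatial(a) -> Tensor:
    """Reverse the three trailing (spatial) axes."""
    a = as_tensor(a)
    return _make(a.data[..., ::-1, ::-1, ::-1].copy(),
                 [(a, lambda g: flip_spatial(g))])


# ---------------------------------------------------------------------------
# 3D convolution family (cross-correlation convention)
# ---------------------------------------------------------------------------

def _conv3d_raw(x, w, stride, pad):
    B, Ci = x.shape[:2]
    Co, _, k = w.shape[0], w.shape[1], w.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x
    osp = tuple((s + 2 * pad - k) // stride + 1 for s in x.shape[2:])
    y = np.zeros((B,) + osp + (Co,), dtype=x.dtype)
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                xs = xp[:, :,
                        kd:kd + stride * (osp[0] - 1) + 1:stride,
                        kh:kh + stride * (osp[1] - 1) + 1:stride,
                        kw:kw + stride * (osp[2] - 1) + 1:stride]
                y += np.tensordot(xs, w[:, :, kd, kh, kw], axes=([1], [1]))
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def _conv3d_xgrad_raw(g, w, x_spatial, stride, pad):
    B, Co = g.shape[:2]
    Ci, k = w.shape[1], w.shape[2]
    padded = tuple(s + 2 * pad for s in x_spatial)
    gx = np.zeros((B, Ci) + padded, dtype=g.dtype)
    osp = g.shape[2:]
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                contrib = np.tensordot(g, w[:, :, kd, kh, kw], axes=([1], [0]))
                contrib = np.moveaxis(contrib, -1, 1)
                gx[:, :,
                   kd:kd + stride * (osp[0] - 1) + 1:stride,
                   kh:kh + stride * (osp[1] - 1) + 1:stride,
                   kw:kw + stride * (osp[2] - 1) + 1:stride] += contrib
    if pad:
        gx = gx[:, :, pad:pad + x_spatial[0], pad:pad + x_spatial[1],
                pad:pad + x_spatial[2]]
    return np.ascontiguousarray(gx)


def _conv3d_wgrad_raw(x, g, k, stride, pad):
    B, Ci = x.shape[:2]
    Co = g.shape[1]
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x
    osp = g.shape[2:]
    gw = np.zeros((Co, Ci, k, k, k), dtype=x.dtype)
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                xs = xp[:, :,
                        kd:kd + stride * (osp[0] - 1) + 1:stride,
                        kh:kh + stride * (osp[1] - 1) + 1:stride,
                        kw:kw + stride * (osp[2] - 1) + 1:stride]
                gw[:, :, kd, kh, kw] = np.tensordot(
                    g, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
    return gw


def conv3d(x, w, stride: int = 1, pad: int = 1) -> Tensor:
    """Cross-correlate ``x`` (B,Ci,D,H,W) with ``w`` (Co,Ci,k,k,k)."""
    x, w = as_tensor(x), as_tensor(w)
    x_spatial = x.shape[2:]
    k = w.shape[2]
    return _make(_conv3d_raw(x.data, w.data, stride, pad), [
        (x, lambda g: conv3d_xgrad(g, w, x_spatial, stride, pad)),
        (w, lambda g: conv3d_wgrad(x, g, k, stride, pad)),
    ])


def conv3d_xgrad(g, w, x_spatial, stride: int = 1, pad: int = 1) -> Tensor:
    """Adjoint of ``conv3d`` in its input argument (a transposed convolution)."""
    g, w = as_tensor(g), as_tensor(w)
    k = w.shape[2]
    return _make(_conv3d_xgrad_raw(g.data, w.data, tuple(x_spatial), stride, pad), [
        (g, lambda gg: conv3d(gg, w, stride, pad)),
        (w, lambda gg: conv3d_wgrad(gg, g, k, stride, pad)),
    ])


def conv3d_wgrad(x, g, k: int, stride: int = 1, pad: int = 1) -> Tensor:
    """Adjoint of ``conv3d`` in its weight argument."""
    x, g = as_tensor(x), as_tensor(g)
    x_spatial = x.shape[2:]
    return _make(_conv3d_wgrad_raw(x.data, g.data, k, stride, pad), [
        (x, lambda gw: conv3d_xgrad(g, gw, x_spatial, stride, pad)),
        (g, lambda gw: conv3d(x, gw, stride, pad)),
    ])


# ---------------------------------------------------------------------------
# resampling pair
# ---------------------------------------------------------------------------

def upsample2(a) -> Tensor:
    """Nearest-neighbour 2x upsampling of the three trailing axes."""
    a = as_tensor(a)
    d = a.data
    out = d.repeat(2, axis=-3).repeat(2, axis=-2).repeat(2, axis=-1)
    return _make(out, [(a, lambda g: blocksum2(g))])


def blocksum2(a) -> Tensor:
    """Sum over non-overlapping 2x2x2 blocks; the adjoint of ``upsample2``."""
    a = as_tensor(a)
    d = a.data
    D, H, W = d.shape[-3:]
    r = d.reshape(d.shape[:-3] + (D // 2, 2, H // 2, 2, W // 2, 2))
    out = r.sum(axis=(-5, -3, -1))
    return _make(out, [(a, lambda g: upsample2(g))])


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs: Sequence[Tensor], grad_output=None,
         create_graph: bool = False) -> list:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients carry tape edges and can be
    differentiated again (used by the gradient penalty).
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grad_output = as_tensor(grad_output)

    topo: list[Tensor] = []
    seen = set()

    def visit(node: Tensor):
        stack = [(node, iter(node._edges))]
        seen.add(id(node))
        while stack:
            cur, it = stack[-1]
            advanced = False
            for parent, _ in it:
                if id(parent) not in seen:
                    seen.add(id(parent))
                    stack.append((parent, iter(parent._edges)))
                    advanced = True
                    break
            if not advanced:
                topo.append(cur)
                stack.pop()

    visit(output)

    grads: dict[int, Tensor] = {id(output): grad_output}
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node._edges:
                pg = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = pg if prev is None else add(prev, pg)
            # keep gradients of requested inputs even if they appear mid-graph
            if any(node is t for t in inputs):
                grads[id(node)] = g

    out = []
    for t in inputs:
        g = grads.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out
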