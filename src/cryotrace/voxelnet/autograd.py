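"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the 3D voxel-classification network: dense and
convolutional primitives with hand-written vector-Jacobian products, plus
elementwise and reduction ops composed into normalization layers and the
softmax cross-entropy loss.  Tensors are wrapped in :class:`Var`; calling
``backward()`` on a scalar loss accumulates ``grad`` on every reachable
variable with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf


class Var:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "parents", "vjp", "requires_grad")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents
        self.vjp = vjp  # callable(grad) -> tuple of parent grads
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        order: list[Var] = []
        seen: set[int] = set()

        def topo(v: Var) -> None:
            stack = [(v, iter(v.parents))]
            seen.add(id(v))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        topo(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node.vjp is None:
                continue
            for parent, pg in zip(node.parents, node.vjp(g)):
                if pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul_scalar(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul_scalar(self, -1.0))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul_scalar(self, -1.0)


def _wrap(x) -> Var:
    return x if isinstance(x, Var) else Var(np.asarray(x, dtype=float))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a: Var, b: Var) -> Var:
    return Var(a.data + b.data, (a, b),
               lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a: Var, b: Var) -> Var:
    return Var(a.data * b.data, (a, b),
               lambda g: (_unbroadcast(g * b.data, a.shape),
                          _unbroadcast(g * a.data, b.shape)))


def mul_scalar(a: Var, s: float) -> Var:
    return Var(a.data * s, (a,), lambda g: (g * s,))


def power(a: Var, p: float) -> Var:
    out = a.data ** p
    return Var(out, (a,), lambda g: (g * p * a.data ** (p - 1),))


def exp(a: Var) -> Var:
    out = np.exp(a.data)
    return Var(out, (a,), lambda g: (g * out,))


def log(a: Var) -> Var:
    return Var(np.log(a.data), (a,), lambda g: (g / a.data,))


def erf(a: Var) -> Var:
    out = _erf(a.data)
    c = 2.0 / np.sqrt(np.pi)
    return Var(out, (a,),
               lambda g: (g * c * np.exp(-a.data * a.data),))


def leaky_relu(a: Var, slope: float = 0.01) -> Var:
    mask = a.data > 0
    out = np.where(mask, a.data, slope * a.data)
    return Var(out, (a,), lambda g: (np.where(mask, g, slope * g),))


def vsum(a: Var, axis=None, keepdims=False) -> Var:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.shape).copy(),)

    return Var(out, (a,), vjp)


def vmean(a: Var, axis=None, keepdims=False) -> Var:
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.shape[ax] for ax in axis]))
    else:
        n = a.shape[axis]
    return mul_scalar(vsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Var, shape) -> Var:
    return Var(a.data.reshape(shape), (a,),
               lambda g: (g.reshape(a.shape),))


def transpose(a: Var, axes) -> Var:
    inv = np.argsort(axes)
    return Var(a.data.transpose(axes), (a,),
               lambda g: (g.transpose(inv),))


def concat(vars_: list[Var], axis: int) -> Var:
    data = np.concatenate([v.data for v in vars_], axis=axis)
    sizes = [v.shape[axis] for v in vars_]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Var(data, tuple(vars_), vjp)


def matmul(a: Var, b: Var) -> Var:
    out = a.data @ b.data

    def vjp(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

    return Var(out, (a, b), vjp)


def softmax(a: Var, axis: int = -1) -> Var:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return Var(out, (a,), vjp)


def log_softmax(a: Var, axis: int = -1) -> Var:
    m = a.data.max(axis=axis, keepdims=True)  # constant shift, exact vjp
    shifted = a.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
    out = a.data - lse
    sm = np.exp(out)

    def vjp(g):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return Var(out, (a,), vjp)


def dropout(a: Var, p: float, rng: np.random.Generator) -> Var:
    if p <= 0:
        return a
    mask = (rng.random(a.shape) >= p) / (1.0 - p)
    return mul(a, Var(mask.astype(a.data.dtype)))


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

_OFFSETS3 = [(dz, dy, dx) for dz in range(3) for dy in range(3)
             for dx in range(3)]


def conv3d(x: Var, w: Var, b: Var) -> Var:
    """3x3x3 convolution, stride 1, zero padding 1.

    ``x``: (B, Cin, D, H, W); ``w``: (Cout, Cin, 3, 3, 3); ``b``: (Cout,).
    """
    B, Cin, D, H, W = x.shape
    Cout = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((B, Cin, 27, D, H, W), dtype=x.data.dtype)
    for o, (dz, dy, dx) in enumerate(_OFFSETS3):
        cols[:, :, o] = xp[:, :, dz:dz + D, dy:dy + H, dx:dx + W]
    cols2 = cols.reshape(B, Cin * 27, D * H * W)
    wf = w.data.reshape(Cout, Cin * 27)
    out = (wf @ cols2).reshape(B, Cout, D, H, W) + b.data.reshape(
        1, Cout, 1, 1, 1)

    def vjp(g):
        gf = g.reshape(B, Cout, D * H * W)
        gw = np.einsum("bct,bkt->ck", gf, cols2).reshape(w.shape)
        gb = g.sum(axis=(0, 2, 3, 4))
        gcols = (wf.T @ gf).reshape(B, Cin, 27, D, H, W)
        gxp = np.zeros_like(xp)
        for o, (dz, dy, dx) in enumerate(_OFFSETS3):
            gxp[:, :, dz:dz + D, dy:dy + H, dx:dx + W] += gcols[:, :, o]
        return (gxp[:, :, 1:-1, 1:-1, 1:-1], gw, gb)

    return Var(out, (x, w, b), vjp)


def conv1x1(x: Var, w: Var, b: Var) -> Var:
    """1x1x1 convolution. ``w``: (Cout, Cin); ``b``: (Cout,)."""
    out = np.einsum("oc,bcdhw->bodhw", w.data, x.data) + b.data.reshape(
        1, -1, 1, 1, 1)

    def vjp(g):
        gw = np.einsum("bodhw,bcdhw->oc", g, x.data)
        gb = g.sum(axis=(0, 2, 3, 4))
        gx = np.einsum("oc,bodhw->bcdhw", w.data, g)
        return (gx, gw, gb)

    return Var(out, (x, w, b), vjp)


def deconv2x2(x: Var, w: Var, b: Var) -> Var:
    """Transposed convolution, kernel 2, stride 2 (doubles each spatial dim).

    ``x``: (B, Cin, D, H, W); ``w``: (Cin, Cout, 2, 2, 2); ``b``: (Cout,).
    """
    B, Cin, D, H, W = x.shape
    Cout = w.shape[1]
    t = np.einsum("bcijk,cdxyz->bdixjykz", x.data, w.data)
    out = t.reshape(B, Cout, 2 * D, 2 * H, 2 * W) + b.data.reshape(
        1, Cout, 1, 1, 1)

    def vjp(g):
        gt = g.reshape(B, Cout, D, 2, H, 2, W, 2)
        gx = np.einsum("bdixjykz,cdxyz->bcijk", gt, w.data)
        gw = np.einsum("bdixjykz,bcijk->cdxyz", gt, x.data)
        gb = g.sum(axis=(0, 2, 3, 4))
        return (gx, gw, gb)

    return Var(out, (x, w, b), vjp)
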