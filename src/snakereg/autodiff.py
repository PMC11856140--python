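"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration network, the spatial-transformer warp and both Adam loops
(network training and per-case field refinement) need gradients of scalar
losses with respect to large dense parameter sets.  This module provides a
compact define-by-run tape: a :class:`Tensor` wraps a float32 ndarray, every
operation records a vector-Jacobian closure, and :meth:`Tensor.backward`
walks the tape in reverse topological order.

Only the operations the package actually uses are implemented.  Heavy
volumetric primitives (3-D convolution, trilinear grid sampling, box and
Gaussian window filters) are custom nodes with hand-written adjoints; see
their docstrings for the conventions.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference / refinement targets)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep tapes overflow Python recursion
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=DTYPE)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=DTYPE))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: tuple[Tensor, ...], vjp) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        out._parents = parents
        out._vjp = vjp
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.astype(DTYPE, copy=False)


# -- elementwise -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    if not isinstance(b, Tensor):
        a = as_tensor(a)
        bv = np.asarray(b, dtype=DTYPE)
        return _node(a.data * bv, (a,), lambda g: (_unbroadcast(g * bv, a.shape),))
    a = as_tensor(a)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)))


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p
    return _node(out, (a,), lambda g: (_unbroadcast(g * p * a.data ** (p - 1), a.shape),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _node(out, (a,), lambda g: (g * (0.5 / out),))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _node(out, (a,), lambda g: (g * (1.0 - out * out),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _node(np.where(mask, a.data, 0.0), (a,), lambda g: (g * mask,))


def gelu(a) -> Tensor:
    """GELU, tanh approximation."""
    a = as_tensor(a)
    c = np.sqrt(2.0 / np.pi).astype(DTYPE)
    inner = mul(add(a, mul(power(a, 3.0), 0.044715)), c)
    return mul(mul(a, 0.5), add(tanh(inner), 1.0))


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data  # ties route gradient to the first argument
    out = np.where(mask, a.data, b.data)
    return _node(out, (a, b),
                 lambda g: (_unbroadcast(g * mask, a.shape), _unbroadcast(g * ~mask, b.shape)))


# -- shape / indexing --------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    return _node(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    # basic indexing (ints/slices) addresses unique cells: plain += suffices;
    # fancy integer arrays may repeat and need unbuffered accumulation
    basic = isinstance(idx, (int, slice)) or (
        isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx))

    def vjp(g):
        out = np.zeros(a.shape, dtype=DTYPE)
        if basic:
            out[idx] += g
        else:
            np.add.at(out, idx, g)
        return (out,)

    return _node(a.data[idx], (a,), vjp)


def take(a, indices: np.ndarray, axis: int = 0) -> Tensor:
    """Integer gather along one axis (used for relative position bias tables)."""
    a = as_tensor(a)
    indices = np.asarray(indices)

    def vjp(g):
        out = np.zeros(a.shape, dtype=DTYPE)
        np.add.at(out, (indices,) if axis == 0 else
                  tuple([slice(None)] * axis + [indices]), g)
        return (out,)

    return _node(np.take(a.data, indices, axis=axis), (a,), vjp)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


def pad(a, pad_width) -> Tensor:
    """Constant zero padding; pad_width as for np.pad."""
    a = as_tensor(a)
    pw = [(int(lo), int(hi)) for lo, hi in pad_width]

    def vjp(g):
        slices = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pw))
        return (g[slices],)

    return _node(np.pad(a.data, pw), (a,), vjp)


def roll(a, shift, axis) -> Tensor:
    a = as_tensor(a)
    shift = tuple(np.atleast_1d(shift))
    axis = tuple(np.atleast_1d(axis))
    neg = tuple(-s for s in shift)
    return _node(np.roll(a.data, shift, axis), (a,), lambda g: (np.roll(g, neg, axis),))


def cumsum(a, axis: int) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return (np.flip(np.cumsum(np.flip(g, axis), axis=axis), axis),)

    return _node(np.cumsum(a.data, axis=axis, dtype=DTYPE), (a,), vjp)


# -- reductions --------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims, dtype=DTYPE)

    def vjp(g):
        g = np.asarray(g, dtype=DTYPE)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).astype(DTYPE, copy=False),)

    return _node(out, (a,), vjp)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = add(a, -a.data.max(axis=axis, keepdims=True))  # detached max: constant shift
    e = exp(shifted)
    return mul(e, power(tsum(e, axis, keepdims=True), -1.0))


# -- matmul ------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        if ga.shape != a.shape:
            ga = _unbroadcast(ga, a.shape)
        if gb.shape != b.shape:
            gb = _unbroadcast(gb, b.shape)
        return (ga, gb)

    return _node(a.data @ b.data, (a, b), vjp)


# -- volumetric primitives ---------------------------------------------------

def conv3d(x, w, b=None, padding: int = 1) -> Tensor:
    """3-D cross-correlation, stride 1.

    x: (Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    Output: (Cout, D', H', W') with D' = D + 2*padding - k + 1.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    cout, cin, k, _, _ = w.shape
    xp = np.pad(x.data, ((0, 0),) + ((padding, padding),) * 3)
    cols = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (Cin, D', H', W', k,k,k)
    sd, sh, sw = cols.shape[1:4]
    cols2 = cols.transpose(1, 2, 3, 0, 4, 5, 6).reshape(sd * sh * sw, cin * k**3)
    wmat = w.data.reshape(cout, cin * k**3)
    out = cols2 @ wmat.T  # (N, Cout)
    if b is not None:
        out = out + b.data
    out = out.T.reshape(cout, sd, sh, sw)

    def vjp(g):
        gmat = g.reshape(cout, -1).T  # (N, Cout)
        gw = (gmat.T @ cols2).reshape(w.shape).astype(DTYPE)
        gx = None
        if _needs_grad(x):
            gcols = (gmat @ wmat).reshape(sd, sh, sw, cin, k, k, k)
            gxp = np.zeros_like(xp)
            for dz in range(k):  # col2im: k^3 shifted accumulations
                for dy in range(k):
                    for dx in range(k):
                        gxp[:, dz:dz + sd, dy:dy + sh, dx:dx + sw] += \
                            gcols[:, :, :, :, dz, dy, dx].transpose(3, 0, 1, 2)
            p = padding
            gx = gxp[:, p:p + x.shape[1], p:p + x.shape[2], p:p + x.shape[3]].astype(DTYPE)
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(1, 2, 3)).astype(DTYPE))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out.astype(DTYPE), parents, vjp)


def _needs_grad(t: Tensor) -> bool:
    return t.requires_grad or t._vjp is not None or bool(t._parents)


def grid_sample(vol, coords) -> Tensor:
    """Trilinear sampling of a channel-first volume at fractional positions.

    vol: (C, D, H, W); coords: (N, 3) in voxel units, order (d, h, w).
    Out-of-bounds positions are border-clamped (replicate edge); the positional
    gradient is zero outside the volume.  Returns (C, N).
    """
    vol, coords = as_tensor(vol), as_tensor(coords)
    C, D, H, W = vol.shape
    nvox = D * H * W
    dims = np.array([D, H, W], dtype=DTYPE)
    cc = np.clip(coords.data, 0.0, dims - 1.0)
    i0 = np.minimum(cc.astype(np.int64), [D - 2, H - 2, W - 2])
    np.maximum(i0, 0, out=i0)
    f = cc - i0  # in [0, 1], float32
    fz, fy, fx = f[:, 0], f[:, 1], f[:, 2]
    gz, gy, gx = 1.0 - fz, 1.0 - fy, 1.0 - fx
    vf = vol.data.reshape(C, -1)
    base = i0[:, 0] * (H * W) + i0[:, 1] * W + i0[:, 2]
    strides = (H * W, W, 1)
    wcomp = ((gz, fz), (gy, fy), (gx, fx))

    corners = []  # (idx, w, (cz, cy, cx))
    for cz in (0, 1):
        for cy in (0, 1):
            for cx in (0, 1):
                idx = base + (cz * strides[0] + cy * strides[1] + cx * strides[2])
                w = wcomp[0][cz] * wcomp[1][cy] * wcomp[2][cx]
                corners.append((idx, w, (cz, cy, cx)))
    N = coords.shape[0]
    out = np.zeros((C, N), dtype=DTYPE)
    tmp = np.empty((C, N), dtype=DTYPE)
    for idx, w, _ in corners:
        np.take(vf, idx, axis=1, out=tmp)
        tmp *= w
        out += tmp

    def vjp(g):  # g: (C, N)
        gvol = None
        gcoords = None
        if _needs_grad(vol):
            idx_all = np.concatenate([c[0] for c in corners])
            w8 = np.stack([w for _, w, _ in corners])  # (8, N)
            gflat = np.empty((C, nvox), dtype=DTYPE)
            for c in range(C):
                gflat[c] = np.bincount(idx_all, weights=(g[c] * w8).ravel(), minlength=nvox)
            gvol = gflat.reshape(vol.shape)
        if _needs_grad(coords):
            inb = ((coords.data > 0) & (coords.data < dims - 1.0)).astype(DTYPE)
            gf = np.zeros((N, 3), dtype=DTYPE)
            buf = np.empty((C, N), dtype=DTYPE)
            for idx, _, (cz, cy, cx) in corners:
                np.take(vf, idx, axis=1, out=buf)
                buf *= g
                gc = buf.sum(axis=0)  # dL/d(weight of this corner)
                sz, sy, sx = (1.0 if cz else -1.0), (1.0 if cy else -1.0), (1.0 if cx else -1.0)
                gf[:, 0] += gc * sz * wcomp[1][cy] * wcomp[2][cx]
                gf[:, 1] += gc * sy * wcomp[0][cz] * wcomp[2][cx]
                gf[:, 2] += gc * sx * wcomp[0][cz] * wcomp[1][cy]
            gcoords = gf * inb
        return (gvol, gcoords)

    return _node(out, (vol, coords), vjp)


def snake_coords(cum, base: np.ndarray, along: int, half: int) -> Tensor:
    """Assemble snake sampling coordinates from cumulative lateral offsets.

    cum: Tensor (2 sides, half, 2 lateral, N) of outward running sums
    (side 0 = minus); base: constant (3, N) identity coordinates; ``along``
    the grid axis the kernel runs along.  Returns (K*N, 3) coordinates,
    tap-major, ordered tap = -half..+half.
    """
    cum = as_tensor(cum)
    lat = [i for i in range(3) if i != along]
    N = base.shape[1]
    K = 2 * half + 1
    out = np.empty((K, N, 3), dtype=DTYPE)
    for t in range(K):
        c = t - half
        out[t, :, along] = base[along] + c
        if c == 0:
            for ax in lat:
                out[t, :, ax] = base[ax]
        else:
            side, step = (1, c - 1) if c > 0 else (0, -c - 1)
            for j, ax in enumerate(lat):
                out[t, :, ax] = base[ax] + cum.data[side, step, j]

    def vjp(g):
        g = g.reshape(K, N, 3)
        gcum = np.zeros(cum.shape, dtype=DTYPE)
        for t in range(K):
            c = t - half
            if c == 0:
                continue
            side, step = (1, c - 1) if c > 0 else (0, -c - 1)
            for j, ax in enumerate(lat):
                gcum[side, step, j] = g[t, :, ax]
        return (gcum,)

    return _node(out.reshape(K * N, 3), (cum,), vjp)


def box_sum(x, window: int) -> Tensor:
    """Windowed sum over a cubic window (zero-padded, 'same' size).

    The operator is linear and self-adjoint (symmetric kernel, zero padding),
    so the adjoint in the backward pass is the operator itself.
    """
    x = as_tensor(x)
    n3 = float(window ** 3)

    def fwd(arr):
        return (ndimage.uniform_filter(arr.astype(np.float64), size=window,
                                       mode="constant") * n3).astype(DTYPE)

    return _node(fwd(x.data), (x,), lambda g: (fwd(g),))


def gaussian_blur(x, sigma: float) -> Tensor:
    """Gaussian filtering (zero-padded); symmetric kernel => self-adjoint."""
    x = as_tensor(x)

    def fwd(arr):
        return ndimage.gaussian_filter(arr.astype(np.float64), sigma,
                                       mode="constant").astype(DTYPE)

    return _node(fwd(x.data), (x,), lambda g: (fwd(g),))


def avg_pool2(x) -> Tensor:
    """2x average pooling of a channel-first (C, D, H, W) grid (even dims)."""
    x = as_tensor(x)
    C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(D, H, W)}")
    r = reshape(x, (C, D // 2, 2, H // 2, 2, W // 2, 2))
    return tmean(r, axis=(2, 4, 6))


def upsample2_nearest(x) -> Tensor:
    """2x nearest-neighbour upsampling of (C, D, H, W)."""
    x = as_tensor(x)
    C, D, H, W = x.shape

    def vjp(g):
        g = g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6))
        return (g.astype(DTYPE),)

    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), 2, axis=3)
    return _node(out, (x,), vjp)


def layer_norm(x, weight, bias, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = tmean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = tmean(mul(xc, xc), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(xc, inv), weight), bias)
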