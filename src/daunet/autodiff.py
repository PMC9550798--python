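"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation network needs: dense
3-D convolutions (unit stride, arbitrary dilation, "same" padding),
stride-2 2x2x2 down-sampling convolutions, pointwise (1x1x1) convolutions,
PReLU, instance normalization, sigmoid, trilinear resizing, concatenation
and the elementwise/reduction arithmetic required by overlap losses.

Feature tensors are laid out channel-first without a batch axis,
``(C, Z, Y, X)`` — the training protocol uses batch size 1 throughout, so
a batch axis would only cost memory. Convolutions are evaluated as a loop
over kernel taps, each tap a single GEMM over all voxels; for the narrow
networks used here this is substantially faster than im2col.

All operations are dtype-preserving: float32 for training speed, float64
when a test wants tight finite-difference gradient checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "conv3d",
    "conv_down2",
    "conv1x1",
    "prelu",
    "instance_norm",
    "sigmoid",
    "resize3",
    "concat",
    "sum_all",
    "linear_resize_matrix",
    "nearest_resize_indices",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Backpropagate d(self)/d(leaf) into every reachable ``.grad``."""
        if self.data.ndim != 0:
            raise ValueError("backward() must start from a scalar tensor")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- scalar / elementwise arithmetic -------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor(a.data / b.data, (a, b), bwd)


def _as_tensor(x, dtype):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def parameter(data):
    return Tensor(np.asarray(data), requires_grad=True)


def constant(data, dtype=None):
    return Tensor(np.asarray(data, dtype=dtype))


def sum_all(t: Tensor) -> Tensor:
    def bwd(g):
        if t.requires_grad:
            t._accum(np.broadcast_to(g, t.shape).astype(t.dtype, copy=True))

    return Tensor(t.data.sum(), (t,), bwd)


# ---------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """3x3x3 convolution, stride 1, zero padding = dilation ("same")."""
    C, Z, Y, X = x.shape
    O = w.shape[0]
    d = int(dilation)
    xp = np.pad(x.data, ((0, 0), (d, d), (d, d), (d, d)))
    out = np.empty((O, Z, Y, X), dtype=x.dtype)
    out[:] = b.data.reshape(O, 1, 1, 1)
    N = Z * Y * X
    for kz in range(3):
        for ky in range(3):
            for kx in range(3):
                sl = xp[:, kz * d:kz * d + Z, ky * d:ky * d + Y, kx * d:kx * d + X]
                out += (w.data[:, :, kz, ky, kx] @ sl.reshape(C, N)).reshape(O, Z, Y, X)

    def bwd(g):
        g2 = g.reshape(O, N)
        if b.requires_grad:
            b._accum(g2.sum(axis=1))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for kz in range(3):
            for ky in range(3):
                for kx in range(3):
                    sl = xp[:, kz * d:kz * d + Z, ky * d:ky * d + Y, kx * d:kx * d + X]
                    if w.requires_grad:
                        gw = g2 @ sl.reshape(C, N).T
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, kz, ky, kx] += gw
                    if gxp is not None:
                        gxp[:, kz * d:kz * d + Z, ky * d:ky * d + Y, kx * d:kx * d + X] += (
                            w.data[:, :, kz, ky, kx].T @ g2
                        ).reshape(C, Z, Y, X)
        if gxp is not None:
            x._accum(gxp[:, d:d + Z, d:d + Y, d:d + X])

    return Tensor(out, (x, w, b), bwd)


def conv_down2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 convolution with stride 2 (the learned pooling substitute)."""
    C, Z, Y, X = x.shape
    if Z % 2 or Y % 2 or X % 2:
        raise ValueError(f"conv_down2 needs even spatial dims, got {(Z, Y, X)}")
    O = w.shape[0]
    Zo, Yo, Xo = Z // 2, Y // 2, X // 2
    # gather the 8 taps of each 2x2x2 cell into the leading axis
    xr = x.data.reshape(C, Zo, 2, Yo, 2, Xo, 2)
    cols = xr.transpose(0, 2, 4, 6, 1, 3, 5).reshape(C * 8, Zo * Yo * Xo)
    w2 = w.data.reshape(O, C * 8)
    out = (w2 @ cols + b.data[:, None]).reshape(O, Zo, Yo, Xo)

    def bwd(g):
        g2 = g.reshape(O, -1)
        if b.requires_grad:
            b._accum(g2.sum(axis=1))
        if w.requires_grad:
            gw = (g2 @ cols.T).reshape(w.shape)
            if w.grad is None:
                w.grad = np.zeros_like(w.data)
            w.grad += gw
        if x.requires_grad:
            gcols = w2.T @ g2
            gx = gcols.reshape(C, 2, 2, 2, Zo, Yo, Xo).transpose(0, 4, 1, 5, 2, 6, 3)
            x._accum(gx.reshape(C, Z, Y, X))

    return Tensor(out, (x, w, b), bwd)


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise convolution: pure channel mixing. w has shape (O, C)."""
    C = x.shape[0]
    sp = x.shape[1:]
    O = w.shape[0]
    out = (w.data @ x.data.reshape(C, -1) + b.data[:, None]).reshape((O,) + sp)

    def bwd(g):
        g2 = g.reshape(O, -1)
        if b.requires_grad:
            b._accum(g2.sum(axis=1))
        if w.requires_grad:
            if w.grad is None:
                w.grad = np.zeros_like(w.data)
            w.grad += g2 @ x.data.reshape(C, -1).T
        if x.requires_grad:
            x._accum((w.data.T @ g2).reshape(x.shape))

    return Tensor(out, (x, w, b), bwd)


# ---------------------------------------------------------------------
# Activations and normalization
# ---------------------------------------------------------------------


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """Parametric ReLU with one learned negative slope per channel."""
    slope = a.data.reshape((-1,) + (1,) * (x.data.ndim - 1))
    pos = np.maximum(x.data, 0)
    neg = np.minimum(x.data, 0)
    out = pos + slope * neg

    def bwd(g):
        if x.requires_grad:
            x._accum(np.where(x.data > 0, g, slope * g))
        if a.requires_grad:
            ga = (g * neg).reshape(x.shape[0], -1).sum(axis=1)
            a._accum(ga.astype(a.dtype))

    return Tensor(out, (x, a), bwd)


def instance_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of one instance."""
    C = x.shape[0]
    flat = x.data.reshape(C, -1)
    mu = flat.mean(axis=1, keepdims=True)
    var = flat.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (flat - mu) * inv
    out = (gain.data[:, None] * xhat + bias.data[:, None]).reshape(x.shape)

    def bwd(g):
        g2 = g.reshape(C, -1)
        if bias.requires_grad:
            bias._accum(g2.sum(axis=1))
        if gain.requires_grad:
            gain._accum((g2 * xhat).sum(axis=1))
        if x.requires_grad:
            gh = g2 * gain.data[:, None]
            m1 = gh.mean(axis=1, keepdims=True)
            m2 = (gh * xhat).mean(axis=1, keepdims=True)
            gx = inv * (gh - m1 - xhat * m2)
            x._accum(gx.reshape(x.shape))

    return Tensor(out, (x, gain, bias), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor(s, (x,), bwd)


# ---------------------------------------------------------------------
# Resizing (trilinear, align-corners endpoint mapping)
# ---------------------------------------------------------------------


@lru_cache(maxsize=256)
def linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix.

    Half-pixel (pixel-centre) mapping ``src = (i + 0.5) * n_in/n_out - 0.5``
    with edge clamping: same-length resizing is the identity, and integer
    scale factors use position-independent periodic weights, which keeps
    the convolutional trunk shift-covariant under upsampling.
    """
    M = np.zeros((n_out, n_in))
    src = _src_coords(n_in, n_out)
    lo = np.floor(src).astype(int)
    whi = src - lo
    lo_c = np.clip(lo, 0, n_in - 1)
    hi_c = np.clip(lo + 1, 0, n_in - 1)
    for i in range(n_out):
        M[i, lo_c[i]] += 1.0 - whi[i]
        M[i, hi_c[i]] += whi[i]
    return M


def nearest_resize_indices(n_in: int, n_out: int) -> np.ndarray:
    src = _src_coords(n_in, n_out)
    return np.clip(np.rint(src).astype(int), 0, n_in - 1)


def _src_coords(n_in: int, n_out: int) -> np.ndarray:
    return (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5


def _apply_axis(data: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(data, axis, 0)
    out = np.tensordot(M, moved, axes=([1], [0]))
    return np.moveaxis(out, 0, axis)


def resize3(x: Tensor, out_shape) -> Tensor:
    """Trilinear resize of the spatial axes of a (C, Z, Y, X) tensor."""
    in_shape = x.shape[1:]
    out_shape = tuple(int(s) for s in out_shape)
    mats = [
        linear_resize_matrix(in_shape[i], out_shape[i]).astype(x.dtype)
        for i in range(3)
    ]
    y = x.data
    for i in range(3):
        if in_shape[i] != out_shape[i]:
            y = _apply_axis(y, mats[i], i + 1)

    def bwd(g):
        if not x.requires_grad:
            return
        for i in reversed(range(3)):
            if in_shape[i] != out_shape[i]:
                g = _apply_axis(g, mats[i].T, i + 1)
        x._accum(g)

    return Tensor(np.ascontiguousarray(y), (x,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(o, o + s)
                t._accum(g[tuple(idx)])

    return Tensor(out, tuple(tensors), bwd)
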