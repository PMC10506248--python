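"""Reverse-mode autodiff on numpy arrays.

Feature maps use NCHW layout throughout. Every op returns a new
:class:`Tensor` whose ``_backward`` closure accumulates gradients into its
parents; :meth:`Tensor.backward` runs the closures in reverse topological
order. Gradients keep the dtype of the forward data, so float64 inputs give
float64 gradients (used by the finite-difference checks in the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """An ndarray plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the whole graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow Python recursion
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    __radd__ = __add__
    __rmul__ = __mul__


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents, backward):
    req = _needs(*parents)
    return Tensor(data, requires_grad=req, _parents=parents if req else (),
                  _backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"add: shape mismatch {a.data.shape} vs {b.data.shape}")
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    """Elementwise (or scalar) product."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def tsum(x: Tensor, axis=None) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.sum(axis=axis)

    def backward(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape))
        else:
            x._accumulate(np.broadcast_to(np.expand_dims(g, axis), x.data.shape))

    return _make(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gi in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(gi)

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution family (stride 1, zero "same" padding)
# ---------------------------------------------------------------------------

def _im2col(x, k):
    """(N,C,H,W) -> (N*H*W, C*k*k) with zero same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


def _col2im(cols, shape, k):
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    p = k // 2
    cols = cols.reshape(n, h, w, c, k, k)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return xp[:, :, p:p + h, p:p + w] if p else xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2-D convolution, stride 1, zero padding preserving spatial size.

    ``weight`` has shape (out_channels, in_channels, k, k) with k odd.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    n, c, h, w = x.data.shape
    o, ci, k, k2 = weight.data.shape
    if ci != c or k != k2:
        raise ValueError(f"conv2d: weight {weight.data.shape} incompatible with input {x.data.shape}")
    cols = _im2col(x.data, k)
    w_row = weight.data.reshape(o, -1)
    y = cols @ w_row.T
    if bias is not None:
        y += bias.data
    out_data = y.reshape(n, h, w, o).transpose(0, 3, 1, 2)

    def backward(g):
        g_col = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, o)
        if weight.requires_grad:
            weight._accumulate((g_col.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g_col.sum(axis=0))
        if x.requires_grad:
            x._accumulate(_col2im(g_col @ w_row, x.data.shape, k))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Per-channel 3x3 convolution; ``weight`` shape (C, k, k)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    n, c, h, w = x.data.shape
    cw, k, _ = weight.data.shape
    if cw != c:
        raise ValueError("depthwise_conv2d: channel mismatch")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    out_data = np.einsum("nchwij,cij->nchw", win, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("nchwij,nchw->cij", win, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
            gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
            wf = weight.data[:, ::-1, ::-1]
            x._accumulate(np.einsum("nchwij,cij->nchw", gwin, wf, optimize=True))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out_data, parents, backward)


def transposed_conv2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2-kernel, stride-2 transposed convolution (exact x2 upsampling).

    With stride equal to the kernel size the output blocks do not overlap, so
    the op is a per-pixel linear map followed by a pixel shuffle. ``weight``
    has shape (in_channels, out_channels, 2, 2).
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    n, c, h, w = x.data.shape
    ci, o, _, _ = weight.data.shape
    if ci != c:
        raise ValueError("transposed_conv2x2: channel mismatch")
    w_mat = weight.data.reshape(c, o * 4)
    y = x.data.transpose(0, 2, 3, 1).reshape(-1, c) @ w_mat  # (N*H*W, O*4)
    y = y.reshape(n, h, w, o, 2, 2).transpose(0, 3, 1, 4, 2, 5).reshape(n, o, 2 * h, 2 * w)
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    def backward(g):
        g_blk = g.reshape(n, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5).reshape(-1, o * 4)
        if weight.requires_grad:
            x_flat = x.data.transpose(0, 2, 3, 1).reshape(-1, c)
            weight._accumulate((x_flat.T @ g_blk).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = (g_blk @ w_mat.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(np.ascontiguousarray(y), parents, backward)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    blk = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    blk = blk.reshape(n, c, h // 2, w // 2, 4)
    idx = blk.argmax(axis=-1)
    out_data = np.take_along_axis(blk, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gb.reshape(n, c, h, w))

    return _make(np.ascontiguousarray(out_data), (x,), backward)


def _bilinear_axis(length_out, length_in, dtype):
    # half-pixel-center convention (matches the common align_corners=False)
    src = (np.arange(length_out, dtype=dtype) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(np.int64), 0, length_in - 1)
    i1 = np.clip(i0 + 1, 0, length_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0).astype(dtype)
    frac = np.where(i1 == i0, 0.0, frac).astype(dtype)
    return i0, i1, frac


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling with half-pixel centers (parameter-free)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    dtype = x.data.dtype if np.issubdtype(x.data.dtype, np.floating) else np.float64
    r0, r1, fr = _bilinear_axis(2 * h, h, dtype)
    c0, c1, fc = _bilinear_axis(2 * w, w, dtype)
    rows = x.data[:, :, r0, :] * (1 - fr)[None, None, :, None] + \
        x.data[:, :, r1, :] * fr[None, None, :, None]
    out_data = rows[:, :, :, c0] * (1 - fc)[None, None, None, :] + \
        rows[:, :, :, c1] * fc[None, None, None, :]

    def backward(g):
        g_rows = np.zeros((n, c, 2 * h, w), dtype=g.dtype)
        np.add.at(g_rows, (slice(None), slice(None), slice(None), c0),
                  g * (1 - fc)[None, None, None, :])
        np.add.at(g_rows, (slice(None), slice(None), slice(None), c1),
                  g * fc[None, None, None, :])
        gx = np.zeros((n, c, h, w), dtype=g.dtype)
        np.add.at(gx, (slice(None), slice(None), r0),
                  g_rows * (1 - fr)[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), r1),
                  g_rows * fr[None, None, :, None])
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain ndarrays updated in place in
    training mode (exponential moving average, unbiased variance like the
    common framework convention).
    """
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    axes = (0, 2, 3)
    m = n * h * w
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                gm = g.mean(axis=axes)[None, :, None, None]
                gxm = (g * xhat).mean(axis=axes)[None, :, None, None]
                x._accumulate(gs * (g - gm - xhat * gxm))
            else:
                x._accumulate(gs * g)

    return _make(out_data, (x, gamma, beta), backward)
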