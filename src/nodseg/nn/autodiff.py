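"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is a define-by-run tape: every operation returns a new
:class:`Tensor` holding a closure that propagates gradients to its parents.
It implements exactly the operations the segmentation network needs --
three-dimensional convolutions (computed in the Fourier domain on the axes
where the kernel extent exceeds one), non-overlapping strided transitions,
batch normalisation, PReLU, pooling, and the elementwise algebra used by
the attention and loss terms.  Everything runs in float32.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # convenience arithmetic used by the losses
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _const(-1.0)))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _const(x):
    return Tensor(np.asarray(x, dtype=np.float32))


def _accum(t, g):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(np.float32, copy=False)


def _node(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- elementwise

def add(a, b):
    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))
    return _node(a.data + b.data, (a, b), bw)


def mul(a, b):
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))
    return _node(a.data * b.data, (a, b), bw)


def div(a, b):
    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))
    return _node(a.data / b.data, (a, b), bw)


def sigmoid(x):
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bw(g):
        _accum(x, g * y * (1.0 - y))
    return _node(y, (x,), bw)


def log(x):
    def bw(g):
        _accum(x, g / x.data)
    return _node(np.log(x.data), (x,), bw)


def clip(x, lo, hi):
    """Clamp values; gradient is passed only where the input was inside."""
    y = np.clip(x.data, lo, hi)
    mask = ((x.data > lo) & (x.data < hi)).astype(np.float32)

    def bw(g):
        _accum(x, g * mask)
    return _node(y, (x,), bw)


def prelu(x, alpha):
    """Channelwise PReLU; `alpha` has shape (C,) against x of shape (N,C,...)."""
    a = alpha.data.reshape((1, -1) + (1,) * (x.data.ndim - 2))
    pos = x.data > 0
    y = np.where(pos, x.data, a * x.data)

    def bw(g):
        _accum(x, np.where(pos, g, a * g))
        da = np.where(pos, 0.0, x.data) * g
        _accum(alpha, da.sum(axis=tuple(i for i in range(x.data.ndim) if i != 1)))
    return _node(y, (x, alpha), bw)


def relu(x):
    pos = x.data > 0

    def bw(g):
        _accum(x, g * pos)
    return _node(np.where(pos, x.data, 0.0), (x,), bw)


def mean_all(x):
    n = x.data.size

    def bw(g):
        _accum(x, np.full_like(x.data, float(g) / n))
    return _node(np.float32(x.data.mean()), (x,), bw)


def sum_all(x):
    def bw(g):
        _accum(x, np.full_like(x.data, float(g)))
    return _node(np.float32(x.data.sum()), (x,), bw)


def global_mean(x):
    """(N, C, Z, Y, X) -> (N, C): squeeze step of the SE block."""
    n = int(np.prod(x.data.shape[2:]))
    y = x.data.mean(axis=(2, 3, 4))

    def bw(g):
        _accum(x, np.broadcast_to((g / n)[:, :, None, None, None], x.data.shape).copy())
    return _node(y, (x,), bw)


def reshape(x, shape):
    old = x.data.shape

    def bw(g):
        _accum(x, g.reshape(old))
    return _node(x.data.reshape(shape), (x,), bw)


def concat(tensors, axis=1):
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _accum(t, g[tuple(sl)])
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def linear(x, w, b=None):
    """x: (N, Cin), w: (Cout, Cin), b: (Cout,)."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data

    def bw(g):
        _accum(x, g @ w.data)
        _accum(w, g.T @ x.data)
        if b is not None:
            _accum(b, g.sum(axis=0))
    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, bw)


# -------------------------------------------------------------- convolutions

_PHASE_CACHE: dict = {}


def _flip_phase(fshape, kk, axes):
    """Per-frequency factor linking rfftn(flip(w)) = conj(rfftn(w)) * phase.

    For a real kernel reversed along the transformed axes (then zero-padded
    to L), W_flip(f) = conj(W(f)) * exp(-2i*pi*f*(k-1)/L) per axis.
    """
    key = (tuple(fshape), tuple(kk), tuple(axes))
    out = _PHASE_CACHE.get(key)
    if out is None:
        ph = None
        for i, (L, k) in enumerate(zip(fshape, kk)):
            n = L // 2 + 1 if i == len(fshape) - 1 else L
            f = np.arange(n)
            p = np.exp(-2j * np.pi * f * (k - 1) / L).astype(np.complex64)
            shape = [1] * len(fshape)
            shape[i] = n
            p = p.reshape(shape)
            ph = p if ph is None else ph * p
        out = _PHASE_CACHE[key] = ph
    return out


def _im2col_T(arr, kk):
    """(B, C, Z, Y, X) -> (C*kvol, B*S) patch matrix with same-padding.

    Built as one contiguous block copy per kernel offset, which is far
    cheaper than a strided gather of the full window view.
    """
    b, c = arr.shape[:2]
    sp = arr.shape[2:]
    pads = [(k - 1) // 2 for k in kk]
    p = np.pad(arr, ((0, 0), (0, 0)) + tuple(
        (q, k - 1 - q) for q, k in zip(pads, kk)))
    kvol = int(np.prod(kk))
    out = np.empty((c, kvol, b) + sp, np.float32)
    j = 0
    for dz in range(kk[0]):
        for dy in range(kk[1]):
            for dx in range(kk[2]):
                sub = p[:, :, dz:dz + sp[0], dy:dy + sp[1], dx:dx + sp[2]]
                out[:, j] = np.moveaxis(sub, 1, 0)
                j += 1
    return out.reshape(c * kvol, b * int(np.prod(sp)))


def _conv_im2col(x, w, b=None):
    co, ci, kz, ky, kx = w.data.shape
    kk = (kz, ky, kx)
    bsz = x.data.shape[0]
    sp = x.data.shape[2:]
    col = _im2col_T(x.data, kk)                     # (Ci*kvol, B*S)
    w2 = w.data.reshape(co, -1)
    yt = w2 @ col                                   # (Co, B*S)
    y = np.ascontiguousarray(
        np.moveaxis(yt.reshape(co, bsz, *sp), 1, 0))
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        g2 = np.ascontiguousarray(np.moveaxis(g, 1, 0)).reshape(co, -1)
        _accum(w, (g2 @ col.T).reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        # dx: correlate g with the channel-transposed, flipped kernel
        wt = np.ascontiguousarray(
            w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)).reshape(ci, -1)
        gcol = _im2col_T(g, kk)                     # (Co*kvol, B*S)
        dxt = wt @ gcol                             # (Ci, B*S)
        _accum(x, np.ascontiguousarray(
            np.moveaxis(dxt.reshape(ci, bsz, *sp), 1, 0)))
    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, bw)


def conv3d(x, w, b=None):
    """Same-padding stride-1 cross-correlation.

    x: (N, Cin, Z, Y, X); w: (Cout, Cin, kz, ky, kx) with odd kernel extents.
    The convolution runs in the Fourier domain over the axes where the
    kernel extent exceeds one; axes the kernel does not extend over are
    folded into the batch dimension.  The input and kernel spectra are
    cached in the closure so the backward pass costs three more transforms.
    """
    kz, ky, kx = w.data.shape[2:]
    if kz == ky == kx == 1:
        return _conv_1x1(x, w, b)
    # small-spatial convolutions run faster as an im2col matrix product on
    # the BLAS; large planes with few channels favour the Fourier route
    if int(np.prod(x.data.shape[2:])) <= 12000:
        return _conv_im2col(x, w, b)
    axes = tuple(ax for ax, k in zip((2, 3, 4), (kz, ky, kx)) if k > 1)
    keep = tuple(ax for ax in (2, 3, 4) if ax not in axes)
    kk = [w.data.shape[ax] for ax in axes]
    fshape = [x.data.shape[ax] + k - 1 for ax, k in zip(axes, kk)]
    n, ci = x.data.shape[:2]
    co = w.data.shape[0]
    conv_dims = [x.data.shape[ax] for ax in axes]
    keep_dims = [x.data.shape[ax] for ax in keep]
    bsz = n * int(np.prod(keep_dims)) if keep_dims else n
    perm = (0, *keep, 1, *axes)
    inv_perm = tuple(np.argsort(perm))
    faxes = tuple(range(2, 2 + len(axes)))

    def fold(arr, c):
        return np.ascontiguousarray(np.transpose(arr, perm)).reshape(
            bsz, c, *conv_dims)

    def unfold(arr, c):
        arr = arr.reshape(n, *keep_dims, c, *conv_dims)
        return np.ascontiguousarray(np.transpose(arr, inv_perm))

    xf = sfft.rfftn(fold(x.data, ci), s=fshape, axes=faxes)
    wt = w.data.reshape(co, ci, *kk)           # drop singleton kernel axes
    wf = sfft.rfftn(wt, s=fshape, axes=faxes)  # unflipped spectrum
    wf_flip = np.conj(wf) * _flip_phase(fshape, kk, axes)
    freq = xf.shape[2:]
    yf = np.einsum("bcf,ocf->bof", xf.reshape(bsz, ci, -1),
                   wf_flip.reshape(co, ci, -1)).reshape(bsz, co, *freq)
    yfull = sfft.irfftn(yf, s=fshape, axes=faxes)
    sl = (slice(None), slice(None)) + tuple(
        slice((k - 1) // 2, (k - 1) // 2 + d) for k, d in zip(kk, conv_dims))
    y = unfold(yfull[sl].astype(np.float32), co)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        gf = sfft.rfftn(fold(g, co), s=fshape, axes=faxes)
        dxf = np.einsum("bof,ocf->bcf", gf.reshape(bsz, co, -1),
                        wf.reshape(co, ci, -1)).reshape(bsz, ci, *freq)
        dxfull = sfft.irfftn(dxf, s=fshape, axes=faxes)
        _accum(x, unfold(dxfull[sl].astype(np.float32), ci))
        dwf = np.einsum("bof,bcf->ocf", np.conj(gf.reshape(bsz, co, -1)),
                        xf.reshape(bsz, ci, -1)).reshape(co, ci, *freq)
        dwfull = sfft.irfftn(dwf, s=fshape, axes=faxes)
        lag = [((np.arange(k) - (k - 1) // 2) % L) for k, L in zip(kk, fshape)]
        dw = dwfull[(slice(None), slice(None)) + np.ix_(*lag)]
        _accum(w, dw.reshape(w.data.shape).astype(np.float32))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, bw)


def _conv_1x1(x, w, b=None):
    ww = w.data.reshape(w.data.shape[0], w.data.shape[1])
    y = np.einsum("nczyx,oc->nozyx", x.data, ww)
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        _accum(x, np.einsum("nozyx,oc->nczyx", g, ww))
        dw = np.einsum("nozyx,nczyx->oc", g, x.data)
        _accum(w, dw.reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
    parents = (x, w) if b is None else (x, w, b)
    return _node(np.ascontiguousarray(y, dtype=np.float32), parents, bw)


def down_conv2x2(x, w, b=None):
    """Non-overlapping (1,2,2)-kernel, (1,2,2)-stride convolution (in-plane halving)."""
    n, c, z, y_, x_ = x.data.shape
    v = x.data.reshape(n, c, z, y_ // 2, 2, x_ // 2, 2)
    ww = w.data.reshape(w.data.shape[0], w.data.shape[1], 2, 2)
    out = np.einsum("nczuavb,ocab->nozuv", v, ww)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        dv = np.einsum("nozuv,ocab->nczuavb", g, ww)
        _accum(x, dv.reshape(n, c, z, y_, x_))
        dw = np.einsum("nozuv,nczuavb->ocab", g, v)
        _accum(w, dw.reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
    parents = (x, w) if b is None else (x, w, b)
    return _node(np.ascontiguousarray(out, dtype=np.float32), parents, bw)


def up_conv2x2(x, w, b=None):
    """Transposed counterpart of :func:`down_conv2x2`; doubles y and x.

    w: (Cin, Cout, 2, 2) following the transposed-convolution convention.
    """
    n, c, z, u, v = x.data.shape
    out = np.einsum("nczuv,coab->nozuavb", x.data, w.data)
    out = out.reshape(n, w.data.shape[1], z, 2 * u, 2 * v)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        gv = g.reshape(n, w.data.shape[1], z, u, 2, v, 2)
        _accum(x, np.einsum("nozuavb,coab->nczuv", gv, w.data))
        _accum(w, np.einsum("nozuavb,nczuv->coab", gv, x.data))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
    parents = (x, w) if b is None else (x, w, b)
    return _node(np.ascontiguousarray(out, dtype=np.float32), parents, bw)


# ------------------------------------------------------------------- pooling

def maxpool2x2(x):
    """Uniform non-overlapping in-plane 2x2 max pooling."""
    n, c, z, y_, x_ = x.data.shape
    v = x.data.reshape(n, c, z, y_ // 2, 2, x_ // 2, 2)
    flat = v.transpose(0, 1, 2, 3, 5, 4, 6).reshape(n, c, z, y_ // 2, x_ // 2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dv = dflat.reshape(n, c, z, y_ // 2, x_ // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6)
        _accum(x, np.ascontiguousarray(dv.reshape(n, c, z, y_, x_)))
    return _node(np.ascontiguousarray(out, dtype=np.float32), (x,), bw)


def maxpool3x3x3_s1(x):
    """Stride-1 same-size 3x3x3 max pooling (the DFFM encoder-branch pool)."""
    pad = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)),
                 constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3, 3), axis=(2, 3, 4))
    flat = win.reshape(win.shape[:5] + (27,))
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        dz, dy, dx_ = np.unravel_index(arg, (3, 3, 3))
        n, c, Z, Y, X = x.data.shape
        nn, cc, zz, yy, xx = np.indices((n, c, Z, Y, X), sparse=True)
        dpad = np.zeros(pad.shape, dtype=np.float32)
        np.add.at(dpad, (nn, cc, zz + dz, yy + dy, xx + dx_), g)
        _accum(x, dpad[:, :, 1:-1, 1:-1, 1:-1])
    return _node(np.ascontiguousarray(out, dtype=np.float32), (x,), bw)


def pool_axis_windows(x, starts, sizes, axis):
    """Max over contiguous windows tiling `axis`; windows given by start/size.

    Implements one axis of central pooling: window sizes are 1, 2 or 3, so
    each output is the max of at most three gathered slices.
    """
    starts = np.asarray(starts)
    sizes = np.asarray(sizes)
    i0 = starts
    i1 = starts + np.minimum(1, sizes - 1)
    i2 = starts + sizes - 1
    g0 = np.take(x.data, i0, axis=axis)
    g1 = np.take(x.data, i1, axis=axis)
    g2 = np.take(x.data, i2, axis=axis)
    stack = np.stack([g0, g1, g2], axis=0)
    arg = stack.argmax(axis=0)
    out = np.take_along_axis(stack, arg[None], axis=0)[0]
    idx_choices = np.stack([i0, i1, i2], axis=0)

    def bw(g):
        sh = [1] * g.ndim
        sh[axis] = len(starts)
        src = np.take_along_axis(
            np.broadcast_to(idx_choices.reshape((3,) + tuple(sh)), (3,) + g.shape),
            arg[None], axis=0)[0]
        dx = np.zeros_like(x.data)
        coords = list(np.ix_(*[np.arange(s) for s in g.shape]))
        coords[axis] = src
        np.add.at(dx, tuple(coords), g)
        _accum(x, dx)
    return _node(np.ascontiguousarray(out, dtype=np.float32), (x,), bw)


# ---------------------------------------------------------------- batch norm

def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.1, eps=1e-5):
    """BatchNorm over (N, spatial) per channel for 5-D inputs.

    `running_mean`/`running_var` are plain ndarrays mutated in place during
    training and used verbatim in evaluation mode.
    """
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    y = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bw(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        gx = g * gamma.data.reshape(shape)
        if training:
            m = x.data.size / x.data.shape[1]
            t1 = gx - gx.mean(axis=axes).reshape(shape) \
                - xhat * (gx * xhat).mean(axis=axes).reshape(shape)
            _accum(x, (t1 * inv.reshape(shape)).astype(np.float32))
            del m
        else:
            _accum(x, gx * inv.reshape(shape))
    return _node(y.astype(np.float32), (x, gamma, beta), bw)


def upsample2x_nearest(x):
    """Nearest-neighbour doubling of the two in-plane axes of (N,C,Z,Y,X)."""
    n, c, z, y_, x_ = x.data.shape
    out = np.broadcast_to(x.data[:, :, :, :, None, :, None],
                          (n, c, z, y_, 2, x_, 2)).reshape(n, c, z, 2 * y_, 2 * x_)

    def bw(g):
        gv = g.reshape(n, c, z, y_, 2, x_, 2)
        _accum(x, gv.sum(axis=(4, 6)))
    return _node(np.ascontiguousarray(out, dtype=np.float32), (x,), bw)
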