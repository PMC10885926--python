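"""Reverse-mode automatic differentiation over numpy arrays.

A tape-free, graph-based autodiff kernel sized for this package's needs:
dense/BLAS matmul, elementwise nonlinearities, reductions, and the three
video-specific primitives (3-D convolution with temporal dilation, average
pooling, temporal linear interpolation).  Arrays keep whatever float dtype
they are given, so loss algebra can run in float64 while network weights
stay float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "avgpool3d",
    "time_interp",
    "softmax",
]


class Tensor:
    """An ndarray plus an optional backward closure into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph construction --------------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None:
                continue
            gs = node._backward(node.grad)
            for parent, g in zip(node._parents, gs):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return add(self, -other)
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- convenience methods --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def relu(self):
        return relu(self)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def tanh(self):
        return tanh(self)

    def sigmoid(self):
        return sigmoid(self)

    def sqrt(self):
        return power(self, 0.5)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ----------------------------------------------------------------------
# elementwise / algebra
# ----------------------------------------------------------------------

def _is_scalar(x) -> bool:
    return isinstance(x, (int, float)) or (
        isinstance(x, np.ndarray) and x.ndim == 0
    )


def add(a, b) -> Tensor:
    # scalar fast path: avoids wrapping python floats as float64 arrays,
    # which would promote large float32 volumes
    if _is_scalar(b) and isinstance(a, Tensor):
        out = a.data + b

        def bws(g):
            return (g,)

        return Tensor._node(out, (a,), bws)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor._node(out, (a, b), bw)


def mul(a, b) -> Tensor:
    if _is_scalar(b) and isinstance(a, Tensor):
        out = a.data * b

        def bws(g):
            return (g * b,)

        return Tensor._node(out, (a,), bws)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def bw(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor._node(out, (a, b), bw)


def div(a, b) -> Tensor:
    if _is_scalar(b) and isinstance(a, Tensor):
        return mul(a, 1.0 / b)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def bw(g):
        return (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
        )

    return Tensor._node(out, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p

    def bw(g):
        return (g * p * a.data ** (p - 1),)

    return Tensor._node(out, (a,), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def bw(g):
        return (g * out,)

    return Tensor._node(out, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        return (g / a.data,)

    return Tensor._node(np.log(a.data), (a,), bw)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)

    def bw(g):
        return (g * (1.0 - out * out),)

    return Tensor._node(out, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        return (g * out * (1.0 - out),)

    return Tensor._node(out, (a,), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)

    def bw(g):
        return (g * (a.data > 0),)

    return Tensor._node(out, (a,), bw)


def instance_norm(x, gamma, beta, axes=(2, 3, 4), eps: float = 1e-5,
                  fuse_relu: bool = False) -> Tensor:
    """Fused normalization over ``axes`` with affine (gamma, beta).

    One primitive instead of ~8 composed ops (optionally with a trailing
    ReLU): the full-volume feature maps dominate memory traffic, so the
    fused forward/backward matters.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (xd - mu) * inv
    out = y * gamma.data + beta.data
    if fuse_relu:
        np.maximum(out, 0, out=out)

    def bw(g):
        if fuse_relu:
            g = g * (out > 0)
        gx = gg = gb = None
        if gamma.requires_grad:
            gg = _unbroadcast(g * y, gamma.data.shape)
        if beta.requires_grad:
            gb = _unbroadcast(g, beta.data.shape)
        if x.requires_grad:
            dy = g * gamma.data
            m1 = dy.mean(axis=axes, keepdims=True)
            m2 = (dy * y).mean(axis=axes, keepdims=True)
            gx = inv * (dy - m1 - y * m2)
        return gx, gg, gb

    return Tensor._node(out, (x, gamma, beta), bw)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically shifted softmax; the max-shift is treated as constant."""
    a = as_tensor(a)
    shift = Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(a - shift)
    return e / e.sum(axis=axis, keepdims=True)


# ----------------------------------------------------------------------
# linear algebra / shape
# ----------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def bw(g):
        ga = gb = None
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            ga = _unbroadcast(ga, a.data.shape)
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            gb = _unbroadcast(gb, b.data.shape)
        return ga, gb

    return Tensor._node(out, (a, b), bw)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(axes):
                gg = np.expand_dims(gg, ax)
        return (np.broadcast_to(gg, a.data.shape).copy(),)

    return Tensor._node(out, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])

    def bw(g):
        return (g.reshape(a.data.shape),)

    return Tensor._node(a.data.reshape(shape), (a,), bw)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    out = np.transpose(a.data, axes)
    inv = None if axes is None else np.argsort(axes)

    def bw(g):
        return (np.transpose(g, inv),)

    return Tensor._node(out, (a,), bw)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out = a.data[idx]

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor._node(out, (a,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out, tuple(tensors), bw)


# ----------------------------------------------------------------------
# video primitives
# ----------------------------------------------------------------------

def conv3d(x, w, bias=None, dilation_t: int = 1, use_numba: bool | None = None,
           ) -> Tensor:
    """3-D convolution, stride 1, 'same' padding, optional temporal dilation.

    ``x``: (B, Cin, T, H, W); ``w``: (Cout, Cin, kt, kh, kw); ``bias``:
    (Cout,) or None.  Two interchangeable engines: direct numba JIT kernels
    (default when numba is available; several times faster on one core) and
    a numpy formulation as a sum of channel-mixing matmuls over kernel
    offsets.  The test suite cross-checks them.
    """
    from . import nb_kernels as nbk

    x, w = as_tensor(x), as_tensor(w)
    if bias is not None:
        bias = as_tensor(bias)
    xd, wd = x.data, w.data
    B, Cin, T, H, W = xd.shape
    Cout, Cin2, kt, kh, kw = wd.shape
    if Cin != Cin2:
        raise ValueError(f"conv3d channel mismatch: input {Cin}, kernel {Cin2}")
    pt, ph, pw = dilation_t * (kt // 2), kh // 2, kw // 2
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    numba_ok = nbk.HAVE_NUMBA if use_numba is None else (use_numba and nbk.HAVE_NUMBA)
    wd_c = wd.astype(xd.dtype, copy=False)
    b_arr = (np.zeros(Cout, dtype=xd.dtype) if bias is None
             else bias.data.astype(xd.dtype, copy=False))

    if numba_ok:
        out = np.empty((B, Cout, T, H, W), dtype=xd.dtype)
        nbk.conv3d_fwd(xp, wd_c, b_arr, out, dilation_t)
    else:
        M = T * H * W
        out = np.zeros((B, Cout, M), dtype=xd.dtype)
        xs_buf = np.empty((B, Cin, M), dtype=xd.dtype)
        xs5 = xs_buf.reshape(B, Cin, T, H, W)
        tmp = np.empty((B, Cout, M), dtype=xd.dtype)
        for it in range(kt):
            ot = it * dilation_t
            for ih in range(kh):
                for iw in range(kw):
                    xs5[...] = xp[:, :, ot:ot + T, ih:ih + H, iw:iw + W]
                    np.matmul(wd_c[:, :, it, ih, iw], xs_buf, out=tmp)
                    out += tmp
        out = out.reshape(B, Cout, T, H, W)
        out += b_arr.reshape(1, Cout, 1, 1, 1)

    def bw(g):
        g = np.ascontiguousarray(g, dtype=xd.dtype)
        gx = gw = gb = None
        if bias is not None and bias.requires_grad:
            gb = g.sum(axis=(0, 2, 3, 4)).astype(bias.data.dtype)
        if numba_ok:
            if w.requires_grad:
                gw = np.zeros_like(wd_c)
                gb_tmp = np.zeros(Cout, dtype=xd.dtype)
                nbk.conv3d_bwd_w(xp, g, gw, gb_tmp, dilation_t)
                gw = gw.astype(wd.dtype, copy=False)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                nbk.conv3d_bwd_x(gxp, wd_c, g, dilation_t)
                gx = np.ascontiguousarray(
                    gxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])
        else:
            M = T * H * W
            gf = g.reshape(B, Cout, M)
            gw_ = np.zeros_like(wd_c) if w.requires_grad else None
            gxp = np.zeros_like(xp) if x.requires_grad else None
            g2 = (np.ascontiguousarray(gf.transpose(1, 0, 2)).reshape(Cout, B * M)
                  if w.requires_grad else None)
            for it in range(kt):
                ot = it * dilation_t
                for ih in range(kh):
                    for iw in range(kw):
                        xs = xp[:, :, ot:ot + T, ih:ih + H, iw:iw + W]
                        if w.requires_grad:
                            x2 = np.ascontiguousarray(
                                xs.reshape(B, Cin, M).transpose(1, 0, 2)
                            ).reshape(Cin, B * M)
                            gw_[:, :, it, ih, iw] = g2 @ x2.T
                        if x.requires_grad:
                            dxs = np.matmul(wd_c[:, :, it, ih, iw].T, gf)
                            gxp[:, :, ot:ot + T, ih:ih + H, iw:iw + W] += (
                                dxs.reshape(B, Cin, T, H, W))
            if w.requires_grad:
                gw = gw_.astype(wd.dtype, copy=False)
            if x.requires_grad:
                gx = np.ascontiguousarray(
                    gxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])
        return (gx, gw) if bias is None else (gx, gw, gb)

    parents = (x, w) if bias is None else (x, w, bias)
    return Tensor._node(out, parents, bw)


def avgpool3d(x, kernel, stride) -> Tensor:
    """Average pooling over (T, H, W).

    Supports kernel == stride along each axis, plus the temporal case
    kernel 2 / stride 1 (replicate-padded at the end so the length is kept).
    """
    x = as_tensor(x)
    kt, kh, kw = kernel
    st, sh, sw = stride
    xd = x.data
    B, C, T, H, W = xd.shape
    pad_t = kt - st if kt > st else 0
    if pad_t:
        xd = np.concatenate([xd, np.repeat(xd[:, :, -1:], pad_t, axis=2)], axis=2)
    Tp = T + pad_t
    To = (Tp - kt) // st + 1
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    scale = 1.0 / (kt * kh * kw)
    out = np.zeros((B, C, To, Ho, Wo), dtype=xd.dtype)
    for it in range(kt):
        for ih in range(kh):
            for iw in range(kw):
                out += xd[:, :, it:it + st * To:st, ih:ih + sh * Ho:sh,
                          iw:iw + sw * Wo:sw]
    out *= scale

    def bw(g):
        gp = np.zeros((B, C, Tp, H, W), dtype=g.dtype)
        gs = g * scale
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    gp[:, :, it:it + st * To:st, ih:ih + sh * Ho:sh,
                       iw:iw + sw * Wo:sw] += gs
        if pad_t:
            gx = gp[:, :, :T].copy()
            gx[:, :, -1] += gp[:, :, T:].sum(axis=2)
        else:
            gx = gp
        return (gx,)

    return Tensor._node(out, (x,), bw)


def time_interp(x, t_out: int) -> Tensor:
    """Linear (align-corners) interpolation along the temporal axis."""
    x = as_tensor(x)
    B, C, T, H, W = x.data.shape
    pos = np.linspace(0.0, T - 1, t_out)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, T - 1)
    w1 = (pos - i0).astype(x.data.dtype)
    M = np.zeros((t_out, T), dtype=x.data.dtype)
    M[np.arange(t_out), i0] += 1.0 - w1
    M[np.arange(t_out), i1] += w1
    out = np.einsum("ot,bcthw->bcohw", M, x.data)

    def bw(g):
        return (np.einsum("ot,bcohw->bcthw", M, g),)

    return Tensor._node(out, (x,), bw)
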