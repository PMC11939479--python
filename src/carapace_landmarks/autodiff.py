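"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operator set the landmark networks need:
broadcast arithmetic, matmul, (grouped) 2-D convolution, batch
normalization, ReLU6, bilinear upsampling, reductions, reshape/concat and
elementwise transcendentals.  Gradients accumulate into ``Tensor.grad``
after calling :meth:`Tensor.backward` on a scalar.

Design notes
------------
* Graphs are built eagerly; each op closes over its inputs and appends a
  backward thunk.  ``backward`` runs a topological sort, so diamond-shaped
  graphs accumulate correctly.
* dtype follows the input arrays (float32 for training, float64 for
  gradient checking); no implicit casts are performed beyond numpy's own
  promotion rules.
* Convolution uses ``sliding_window_view`` + batched matmul (im2col); the
  input-gradient is the standard col2im scatter-add.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "batch_norm",
    "upsample_bilinear",
    "concat",
    "where",
    "gradcheck",
]


class Tensor:
    """A numpy array with an optional gradient and a backward graph node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # Make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops.
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g):
        # out-of-place accumulation: thunks may hand the same array to
        # several parents (e.g. residual adds), so never mutate ``g``.
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _grad_add)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, _grad_sub)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _grad_mul)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide, _grad_div)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = _make(np.power(self.data, p), (self,))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g * p * np.power(self.data, p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def bw(g):
            if _needs(self):
                self._accumulate(g @ other.data.T)
            if _needs(other):
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out = _make(np.exp(self.data), (self,))

        def bw(g):
            if _needs(self):
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))

        def bw(g):
            if _needs(self):
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))

        def bw(g):
            if _needs(self):
                self._accumulate(g * np.sign(self.data))

        out._backward = bw
        return out

    def relu6(self):
        out = _make(np.minimum(np.maximum(self.data, 0.0), 6.0), (self,))
        mask = (self.data > 0.0) & (self.data < 6.0)

        def bw(g):
            if _needs(self):
                self._accumulate(g * mask)

        out._backward = bw
        return out

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def bw(g):
            if _needs(self):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        orig = self.data.shape

        def bw(g):
            if _needs(self):
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    def max(self):
        """Detached maximum (used for numerically stable softmax shifts)."""
        return float(self.data.max())


# ---------------------------------------------------------------------------
# helpers


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


def _make(data, parents) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _grad_add(a, b, out, g):
    if _needs(a):
        a._accumulate(_unbroadcast(g, a.data.shape))
    if _needs(b):
        b._accumulate(_unbroadcast(g, b.data.shape))


def _grad_sub(a, b, out, g):
    if _needs(a):
        a._accumulate(_unbroadcast(g, a.data.shape))
    if _needs(b):
        b._accumulate(_unbroadcast(-g, b.data.shape))


def _grad_mul(a, b, out, g):
    if _needs(a):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
    if _needs(b):
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))


def _grad_div(a, b, out, g):
    if _needs(a):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
    if _needs(b):
        b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))


def _binary(a, b, fwd, grad) -> Tensor:
    a = _as_tensor(a)
    b = _as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    out._backward = lambda g: grad(a, b, out, g)
    return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _needs(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def where(cond, a, b) -> Tensor:
    """Elementwise select with a constant (non-differentiated) condition."""
    cond = np.asarray(cond, dtype=bool)
    a = _as_tensor(a)
    b = _as_tensor(b)
    out = _make(np.where(cond, a.data, b.data), (a, b))

    def bw(g):
        if _needs(a):
            a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
        if _needs(b):
            b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution


def _im2col(x, kh, kw, stride, padding):
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride], x.shape


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    ``x``: (N, C, H, W); ``w``: (Cout, C//groups, kh, kw).  Pointwise
    (1x1, ungrouped) and depthwise kernels take dedicated fast paths; the
    general case goes through im2col.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Co, Cg, kh, kw = wd.shape
    if C // groups != Cg or Co % groups:
        raise ValueError(
            f"incompatible conv shapes: x has {C} channels, kernel expects "
            f"{Cg}x{groups} (groups={groups}, out={Co})")
    if kh == 1 and kw == 1 and groups == 1 and padding == 0 and stride == 1:
        return _conv1x1(x, w)
    if groups == C and Co == C and Cg == 1:
        return _conv_depthwise(x, w, stride, padding)
    return _conv_im2col(x, w, stride, padding, groups)


def _conv1x1(x: Tensor, w: Tensor) -> Tensor:
    """Pointwise conv as a batched matmul: (Co,C) @ (N,C,H*W)."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Co = wd.shape[0]
    w2 = wd.reshape(Co, C)
    xr = xd.reshape(N, C, H * W)
    out = _make(np.matmul(w2, xr).reshape(N, Co, H, W), (x, w))

    def bw(g):
        gr = g.reshape(N, Co, H * W)
        if _needs(w):
            dw = np.matmul(gr, xr.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(wd.shape))
        if _needs(x):
            dx = np.matmul(w2.T, gr).reshape(N, C, H, W)
            x._accumulate(dx)

    out._backward = bw
    return out


def _conv_depthwise(x: Tensor, w: Tensor, stride: int,
                    padding: int) -> Tensor:
    """Depthwise conv as a sum of shifted, per-channel-scaled slices."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    _, _, kh, kw = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding),
                     (padding, padding))) if padding else xd
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out_d = np.zeros((N, C, Ho, Wo), dtype=xd.dtype)
    for a in range(kh):
        for b in range(kw):
            out_d += (wd[:, 0, a, b][:, None, None]
                      * xp[:, :, a:a + stride * Ho:stride,
                           b:b + stride * Wo:stride])
    out = _make(out_d, (x, w))

    def bw(g):
        if _needs(w):
            dw = np.empty_like(wd)
            for a in range(kh):
                for b in range(kw):
                    sl = xp[:, :, a:a + stride * Ho:stride,
                            b:b + stride * Wo:stride]
                    dw[:, 0, a, b] = (g * sl).sum(axis=(0, 2, 3))
            w._accumulate(dw)
        if _needs(x):
            dxp = np.zeros_like(xp)
            for a in range(kh):
                for b in range(kw):
                    dxp[:, :, a:a + stride * Ho:stride,
                        b:b + stride * Wo:stride] += (
                        wd[:, 0, a, b][:, None, None] * g)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = bw
    return out


def _conv_im2col(x: Tensor, w: Tensor, stride: int, padding: int,
                 groups: int) -> Tensor:
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Co, Cg, kh, kw = wd.shape
    win, padded_shape = _im2col(xd, kh, kw, stride, padding)
    _, _, Ho, Wo, _, _ = win.shape
    # (g, N*Ho*Wo, Cg*kh*kw) @ (g, Cg*kh*kw, Co/g)
    cols = win.reshape(N, groups, Cg, Ho, Wo, kh * kw)
    cols = cols.transpose(1, 0, 3, 4, 2, 5).reshape(
        groups, N * Ho * Wo, Cg * kh * kw)
    wmat = wd.reshape(groups, Co // groups, Cg * kh * kw)
    prod = np.matmul(cols, wmat.transpose(0, 2, 1))
    out = prod.reshape(groups, N, Ho, Wo, Co // groups)
    out = out.transpose(1, 0, 4, 2, 3).reshape(N, Co, Ho, Wo)
    result = _make(np.ascontiguousarray(out), (x, w))

    def bw(g):
        gg = np.ascontiguousarray(g).reshape(N, groups, Co // groups, Ho, Wo)
        gg = gg.transpose(1, 0, 3, 4, 2).reshape(
            groups, N * Ho * Wo, Co // groups)
        if _needs(w):
            dwmat = np.matmul(gg.transpose(0, 2, 1), cols)
            w._accumulate(dwmat.reshape(wd.shape))
        if _needs(x):
            dcols = np.matmul(gg, wmat)  # (g, N*Ho*Wo, Cg*kh*kw)
            dcols = dcols.reshape(groups, N, Ho, Wo, Cg, kh, kw)
            dcols = dcols.transpose(1, 0, 4, 2, 3, 5, 6).reshape(
                N, C, Ho, Wo, kh, kw)
            x._accumulate(_col2im(dcols, xd.shape, padded_shape, kh, kw,
                                  stride, padding))

    result._backward = bw
    return result


def _col2im(dcols, x_shape, padded_shape, kh, kw, stride, padding):
    """Scatter-add window gradients back onto the (padded) input."""
    dxp = np.zeros(padded_shape, dtype=dcols.dtype)
    Ho, Wo = dcols.shape[2], dcols.shape[3]
    for a in range(kh):
        for b in range(kw):
            dxp[:, :, a:a + stride * Ho:stride,
                b:b + stride * Wo:stride] += dcols[..., a, b]
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp


# ---------------------------------------------------------------------------
# batch normalization


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, C, H, W) or (N, C).

    In training mode the batch statistics are used and the running buffers
    are updated in place (outside the autodiff graph); in eval mode the
    running buffers are used, making the op a per-sample affine map.
    """
    xd = x.data
    axes = (0,) if xd.ndim == 2 else (0, 2, 3)
    shape = [1] * xd.ndim
    shape[1] = xd.shape[1]
    if training:
        mu = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        n = xd.size // xd.shape[1]
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
        n = None
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(shape)) * inv_std.reshape(shape)
    out = _make(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape),
                (x, gamma, beta))

    def bw(g):
        if _needs(gamma):
            gamma._accumulate((g * xhat).sum(axis=axes))
        if _needs(beta):
            beta._accumulate(g.sum(axis=axes))
        if _needs(x):
            gs = g * gamma.data.reshape(shape)
            if training:
                m1 = gs.mean(axis=axes).reshape(shape)
                m2 = (gs * xhat).mean(axis=axes).reshape(shape)
                dx = inv_std.reshape(shape) * (gs - m1 - xhat * m2)
            else:
                dx = gs * inv_std.reshape(shape)
            x._accumulate(dx)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# bilinear upsampling


def _linear_weights(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Interpolation matrix mapping a length-``n_in`` axis to ``n_out``.

    Endpoints map to endpoints (the convention of bilinear upsamplers that
    align corner samples), so the operation is exact on linear ramps.
    """
    W = np.zeros((n_out, n_in), dtype=dtype)
    if n_out == 1 or n_in == 1:
        W[:, 0] = 1.0
        return W
    scale = (n_in - 1) / (n_out - 1)
    for o in range(n_out):
        src = o * scale
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        f = src - i0
        W[o, i0] += 1.0 - f
        W[o, i1] += f
    return W


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling of (N, C, H, W) to (N, C, out_h, out_w)."""
    xd = x.data
    Wr = _linear_weights(xd.shape[2], out_h, xd.dtype)
    Wc = _linear_weights(xd.shape[3], out_w, xd.dtype)
    out = _make(np.einsum("oi,ncij,pj->ncop", Wr, xd, Wc, optimize=True),
                (x,))

    def bw(g):
        if _needs(x):
            x._accumulate(np.einsum("oi,ncop,pj->ncij", Wr, g, Wc,
                                    optimize=True))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# gradient checking


def gradcheck(fn, inputs, eps: float = 1e-5) -> float:
    """Max relative error between autodiff and central finite differences.

    ``fn`` maps the list of input Tensors to a scalar Tensor; inputs should
    be float64 for meaningful comparisons.
    """
    for t in inputs:
        t.zero_grad()
    out = fn(*inputs)
    out.backward()
    worst = 0.0
    for t in inputs:
        analytic = t.grad if t.grad is not None else np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn(*inputs).data)
            flat[i] = orig - eps
            lo = float(fn(*inputs).data)
            flat[i] = orig
            num[i] = (hi - lo) / (2 * eps)
        num = num.reshape(t.data.shape)
        denom = np.maximum(np.abs(num) + np.abs(analytic), 1e-8)
        worst = max(worst, float(np.max(np.abs(num - analytic) / denom)))
    return worst
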