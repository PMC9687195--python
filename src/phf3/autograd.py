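"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: every operation on :class:`Tensor` records its
parents and a closure that maps the output gradient to parent gradients.
``Tensor.backward()`` topologically sorts the tape and accumulates gradients
into ``.grad`` (a plain ndarray) of every tensor with ``requires_grad=True``.

All computation is single precision by default; gradients are taken through
every operation explicitly (no implicit differentiation anywhere), which is
what makes the unrolled Newton–Schulz iteration in the covariance-pooling
head differentiable end to end.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

DEFAULT_DTYPE = np.float32

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "layer_norm",
    "batch_norm2d",
    "no_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (e.g. running-stat updates)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor dispatch to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(DEFAULT_DTYPE)  # float64 inputs keep their precision
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = ()
        out._backward = None
        out.requires_grad = False
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (27-block stage)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))

        self.grad = grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + pgrad

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return (
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            )

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            return (
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            )

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            return (
                (self, _unbroadcast(g / other.data, self.data.shape)),
                (other, _unbroadcast(-g * self.data / (other.data**2), other.data.shape)),
            )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor._make(out_data, (self,), bw)

    # -- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (
                (self, _unbroadcast(ga, a.shape)),
                (other, _unbroadcast(gb, b.shape)),
            )

        return Tensor._make(out_data, (self, other), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(out_data, (self,), bw)

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            return ((self, g.reshape(orig)),)

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def bw(g):
            gx = np.zeros(shape, dtype=g.dtype)
            np.add.at(gx, idx, g)
            return ((self, gx),)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                gx = np.broadcast_to(g, shape).copy()
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                gx = np.broadcast_to(g, shape).copy()
            return ((self, gx),)

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            return ((self, g * (self.data > 0)),)

        return Tensor._make(out_data, (self,), bw)

    def gelu(self):
        # exact GELU: x * Phi(x)
        x = self.data
        phi = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0, dtype=x.dtype)))
        out_data = (x * phi).astype(x.dtype)

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            return ((self, g * (phi + x * pdf).astype(x.dtype)),)

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            return ((self, g / self.data),)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            return ((self, g * 0.5 / out_data),)

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis=-1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return ((self, y * (g - dot)),)

        return Tensor._make(y, (self,), bw)

    def log_softmax(self, axis=-1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        shifted = x - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def bw(g):
            return ((self, g - soft * g.sum(axis=axis, keepdims=True)),)

        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._make(out_data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# Convolution via im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh, kw, sh, sw, ph, pw):
    """[N,C,H,W] -> columns [N, Ho*Wo, C*kh*kw] plus output geometry."""
    n, c, h, w = x.shape
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    v = v[:, :, ::sh, ::sw]  # [N,C,Ho,Wo,kh,kw]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, sh, sw, ph, pw, ho, wo):
    n, c, h, w = xshape
    gp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            gp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += d[:, :, i, j]
    if ph or pw:
        gp = gp[:, :, ph : ph + h, pw : pw + w]
    return gp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding=0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout; supports grouped/depthwise kernels."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    n, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {cin} channels, "
            f"weight expects {cin_g * groups} (groups={groups})"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    if ho <= 0 or wo <= 0:
        raise ValueError(f"conv2d produces non-positive output size ({ho}x{wo})")

    if groups == 1:
        wmat = weight.data.reshape(cout, -1)
        out = cols @ wmat.T  # [N, Ho*Wo, Cout]
    else:
        cols_g = cols.reshape(n, ho * wo, groups, cin_g * kh * kw)
        wmat = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
        out = np.einsum("npgk,gok->npgo", cols_g, wmat).reshape(n, ho * wo, cout)
    out = out.transpose(0, 2, 1).reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gout = g.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # [N,Ho*Wo,Cout]
        grads = []
        if groups == 1:
            wmat_ = weight.data.reshape(cout, -1)
            dcols = gout @ wmat_  # [N,HoWo,Cin*kh*kw]
            dw = np.einsum("npo,npk->ok", gout, cols).reshape(weight.data.shape)
        else:
            gout_g = gout.reshape(n, ho * wo, groups, cout // groups)
            cols_g = cols.reshape(n, ho * wo, groups, cin_g * kh * kw)
            wmat_ = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
            dcols = np.einsum("npgo,gok->npgk", gout_g, wmat_).reshape(n, ho * wo, -1)
            dw = np.einsum("npgo,npgk->gok", gout_g, cols_g).reshape(weight.data.shape)
        dx = _col2im(dcols, x.data.shape, kh, kw, sh, sw, ph, pw, ho, wo)
        grads.append((x, dx))
        grads.append((weight, dw))
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._make(out.astype(x.data.dtype, copy=False), parents, bw)


def max_pool2d(x: Tensor, kernel=3, stride=2, padding=1) -> Tensor:
    kh = kw = kernel
    sh = sw = stride
    ph = pw = padding
    n, c, h, w = x.data.shape
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                constant_values=-np.inf)
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    v = v[:, :, ::sh, ::sw].reshape(n, c, ho, wo, kh * kw)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=g.dtype)
        ii, jj = np.unravel_index(idx, (kh, kw))
        oy, ox = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oy[None, None] * sh + ii
        colz = ox[None, None] * sw + jj
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(gx, (nn_[..., None, None], cc[..., None, None], rows, colz), g)
        if ph or pw:
            gx = gx[:, :, ph : ph + h, pw : pw + w]
        return ((x, gx),)

    return Tensor._make(out.astype(x.data.dtype, copy=False), (x,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd
    out = xhat * gamma.data + beta.data
    d = x.data.shape[-1]

    def bw(g):
        gg = g * gamma.data
        dx = invstd * (
            gg
            - gg.mean(axis=-1, keepdims=True)
            - xhat * (gg * xhat).mean(axis=-1, keepdims=True)
        )
        red = tuple(range(g.ndim - 1))
        return (
            (x, dx.astype(x.data.dtype, copy=False)),
            (gamma, (g * xhat).sum(axis=red)),
            (beta, g.sum(axis=red)),
        )

    _ = d
    return Tensor._make(out.astype(x.data.dtype, copy=False), (x, gamma, beta), bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,H,W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * invstd[None, :, None, None]
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def bw(g):
        gg = g * gamma.data[None, :, None, None]
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            mean_gg = gg.mean(axis=(0, 2, 3), keepdims=True)
            mean_ggx = (gg * xhat).mean(axis=(0, 2, 3), keepdims=True)
            dx = invstd[None, :, None, None] * (gg - mean_gg - xhat * mean_ggx)
            _ = m
        else:
            dx = gg * invstd[None, :, None, None]
        return (
            (x, dx.astype(x.data.dtype, copy=False)),
            (gamma, (g * xhat).sum(axis=(0, 2, 3))),
            (beta, g.sum(axis=(0, 2, 3))),
        )

    return Tensor._make(out.astype(x.data.dtype, copy=False), (x, gamma, beta), bw)
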