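"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations the detection network and its losses
need: broadcasting arithmetic, matmul, the usual pointwise nonlinearities,
axis reductions, 2-D convolution via im2col/GEMM, batch normalization,
nearest-neighbour up-sampling and gather at instance center cells.  All
data is float32; gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted graph.

Graph recording can be suspended with :func:`no_grad` (used for validation
and inference passes).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Suspend graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A float32 array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data, dtype=np.float32)
        if data.ndim and not data.flags["C_CONTIGUOUS"]:
            data = np.ascontiguousarray(data)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # own a private copy: callers may pass shared/viewed arrays
            self.grad = np.array(grad, dtype=np.float32)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(
                    self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,),
                            lambda g: a.requires_grad and a._accum(-g))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data),
                                      b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bwd(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- pointwise nonlinearities -----------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
        return Tensor._make(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def softplus(self):
        a = self
        out = np.logaddexp(0.0, a.data)
        return Tensor._make(
            out, (a,), lambda g: a._accum(g / (1.0 + np.exp(-a.data))))

    def exp(self):
        a = self
        e = np.exp(a.data)
        return Tensor._make(e, (a,), lambda g: a._accum(g * e))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,),
                            lambda g: a._accum(g / a.data))

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: a._accum(g * sign))

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient is passed only where not clipped."""
        a = self
        out = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask *= a.data > lo
        if hi is not None:
            mask *= a.data < hi
        return Tensor._make(out, (a,), lambda g: a._accum(g * mask))

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Max along ``axis``; ties share the gradient equally."""
        a = self
        out = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)
        out_data = out if keepdims else np.squeeze(out, axis=axis)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(g * mask)

        return Tensor._make(out_data, (a,), bwd)

    def reshape(self, *shape):
        a = self
        orig = a.data.shape
        return Tensor._make(a.data.reshape(*shape), (a,),
                            lambda g: a._accum(g.reshape(orig)))

    def __getitem__(self, idx):
        a = self
        out = a.data[idx]

        def bwd(g):
            dx = np.zeros_like(a.data)
            np.add.at(dx, idx, g)
            a._accum(dx)

        return Tensor._make(out, (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(*axes), (a,),
                            lambda g: a._accum(g.transpose(*inv)))


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    parts = [astensor(t) for t in tensors]
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for p, piece in zip(parts, np.split(g, splits, axis=axis)):
            if p.requires_grad:
                p._accum(piece)

    return Tensor._make(np.concatenate([p.data for p in parts], axis=axis),
                        parts, bwd)


# -- convolution and friends ----------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - k) // stride + 1
    ow = (x.shape[3] - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # n,c,oh,ow,k,k
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel."""
    n, c, h, w = x.data.shape
    f, c_w, k, _ = weight.data.shape
    assert c == c_w, f"channel mismatch: input {c}, weight {c_w}"
    cols, oh, ow = _im2col(x.data, k, stride, padding)
    w_mat = weight.data.reshape(f, c * k * k)
    out = cols @ w_mat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(n, oh, ow, f).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        g_flat = np.ascontiguousarray(
            g.transpose(0, 2, 3, 1).reshape(n * oh * ow, f))
        if bias is not None and bias.requires_grad:
            bias._accum(g_flat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((g_flat.T @ cols).reshape(weight.data.shape))
        if x.requires_grad:
            dcols = (g_flat @ w_mat).reshape(n, oh, ow, c, k, k)
            hp, wp = h + 2 * padding, w + 2 * padding
            dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            view = dxp.transpose(0, 2, 3, 1)             # n,hp,wp,c view
            for ki in range(k):
                for kj in range(k):
                    view[:, ki:ki + stride * oh:stride,
                         kj:kj + stride * ow:stride] += dcols[:, :, :, :,
                                                              ki, kj]
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dxp)

    return Tensor._make(out, parents, bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W); updates running stats."""
    n, c, h, w = x.data.shape
    m = n * h * w
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(1, m - 1))  # unbiased
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (dxhat - s1 / m - xhat * s2 / m) \
                    * invstd[None, :, None, None]
            else:
                dx = dxhat * invstd[None, :, None, None]
            x._accum(dx.astype(np.float32))

    return Tensor._make(out, (x, gamma, beta), bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    a = x
    n, c, h, w = a.data.shape
    out = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (a,), bwd)


def _bilinear_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Double one spatial axis with 2× bilinear interpolation (edges clamped).

    out[2i] = 0.75·x[i] + 0.25·x[i−1];  out[2i+1] = 0.75·x[i] + 0.25·x[i+1].
    """
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x + 0.25 * prev
    out[..., 1::2] = 0.75 * x + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _bilinear_axis_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose of :func:`_bilinear_axis` (the exact backward pass)."""
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    din = 0.75 * (ge + go)
    din[..., :-1] += 0.25 * ge[..., 1:]
    din[..., 0] += 0.25 * ge[..., 0]
    din[..., 1:] += 0.25 * go[..., :-1]
    din[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(din, -1, axis)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Double both spatial axes of an NCHW tensor by bilinear interpolation."""
    a = x
    out = _bilinear_axis(_bilinear_axis(a.data, 2), 3)

    def bwd(g):
        a._accum(_bilinear_axis_T(_bilinear_axis_T(g, 3), 2)
                 .astype(np.float32))

    return Tensor._make(out, (a,), bwd)


def gather_centers(x: Tensor, n_idx: np.ndarray, y_idx: np.ndarray,
                   x_idx: np.ndarray) -> Tensor:
    """Read head values at instance center cells: (N,C,H,W) → (K, C)."""
    a = x
    n_idx = np.asarray(n_idx, dtype=np.intp)
    y_idx = np.asarray(y_idx, dtype=np.intp)
    x_idx = np.asarray(x_idx, dtype=np.intp)
    out = a.data[n_idx, :, y_idx, x_idx]

    def bwd(g):
        dx = np.zeros_like(a.data)
        c = a.data.shape[1]
        np.add.at(dx, (n_idx[:, None], np.arange(c)[None, :],
                       y_idx[:, None], x_idx[:, None]), g)
        a._accum(dx)

    return Tensor._make(out, (a,), bwd)
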