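"""Neural-network modules built on the autodiff engine.

Provides the building blocks of the detector: convolution, batch
normalization, basic residual blocks, CBAM channel+spatial attention and a
deformable 3×3 convolution (learned per-position sampling offsets, bilinear
interpolation).  Weight initialization is He-normal and always drawn from
an explicit ``numpy.random.Generator`` so that model construction is fully
seeded.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, astensor, batch_norm, concat, conv2d,
                       gather_centers, no_grad, upsample_bilinear2x, upsample_nearest2x)

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "ConvBNReLU", "BasicBlock", "CBAM",
    "DeformConv2d", "Tensor", "astensor", "no_grad", "concat",
    "upsample_nearest2x", "upsample_bilinear2x", "gather_centers",
]


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + name: b.copy()
                      for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buf:"):
                buf = buffers[key[4:]]
                buf[...] = value
            else:
                params[key].data = np.ascontiguousarray(value,
                                                        dtype=np.float32)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int,
                 kernel: int = 3, stride: int = 1, padding: int | None = None,
                 bias: bool = True, bias_init: float = 0.0,
                 zero_init: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=np.float32) \
            if zero_init else _he_normal(rng, (out_ch, in_ch, kernel, kernel),
                                         fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.full(out_ch, bias_init, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training, self.momentum,
                          self.eps)


class ConvBNReLU(Module):
    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=1):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, kernel, stride, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class BasicBlock(Module):
    """Two 3×3 conv-BN layers with a residual connection (projection when
    the channel count or stride changes)."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(rng, in_ch, out_ch, 3, stride, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3, 1, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.project = Conv2d(rng, in_ch, out_ch, 1, stride, padding=0,
                                  bias=False)
            self.project_bn = BatchNorm2d(out_ch)
        else:
            self.project = None

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.project is None \
            else self.project_bn(self.project(x))
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + identity).relu()


class CBAM(Module):
    """Channel-then-spatial attention gating; output shape = input shape.

    Channel attention: shared two-layer 1×1-conv MLP on global average- and
    max-pooled channel statistics, summed, sigmoid-gated.  Spatial
    attention: 7×7 convolution over the channelwise mean and max maps,
    sigmoid-gated.  Every gate value lies strictly in (0, 1).
    """

    def __init__(self, rng, channels: int, reduction: int = 4,
                 spatial_kernel: int = 7):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(rng, channels, hidden, 1, padding=0)
        self.fc2 = Conv2d(rng, hidden, channels, 1, padding=0)
        self.spatial = Conv2d(rng, 2, 1, spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        gate_c = (self.fc2(self.fc1(avg).relu())
                  + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = x * gate_c
        ch_avg = x.mean(axis=1, keepdims=True)
        ch_max = x.max(axis=1, keepdims=True)
        gate_s = self.spatial(concat([ch_avg, ch_max], axis=1)).sigmoid()
        return x * gate_s


class DeformConv2d(Module):
    """3×3 deformable convolution: a plain conv predicts per-position
    sampling offsets, the input is bilinearly sampled there, then the main
    kernel is applied (GEMM on the sampled columns).  Offsets are
    zero-initialized so the layer starts as an ordinary convolution."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        super().__init__()
        self.k = 3
        self.offset_conv = Conv2d(rng, in_ch, 2 * self.k * self.k, 3,
                                  zero_init=True)
        fan_in = in_ch * self.k * self.k
        self.weight = Tensor(_he_normal(rng, (out_ch, in_ch, 3, 3), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        offsets = self.offset_conv(x)
        return _deform_sample_conv(x, offsets, self.weight, self.bias, self.k)


def _deform_sample_conv(x: Tensor, offsets: Tensor, weight: Tensor,
                        bias: Tensor, k: int) -> Tensor:
    n, c, h, w = x.data.shape
    f = weight.data.shape[0]
    kk = k * k
    # base sampling grid: kernel tap (ki, kj) centred at each output pixel
    ys, xs = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    taps = np.arange(k, dtype=np.float32) - (k - 1) / 2.0
    off = offsets.data.reshape(n, kk, 2, h, w)
    py = ys[None, None] + taps.repeat(k)[None, :, None, None] + off[:, :, 0]
    px = xs[None, None] + np.tile(taps, k)[None, :, None, None] + off[:, :, 1]
    inside_y = (py > 0.0) & (py < h - 1.0)   # clipped taps: no positional grad
    inside_x = (px > 0.0) & (px < w - 1.0)
    py = np.clip(py, 0.0, h - 1.0)
    px = np.clip(px, 0.0, w - 1.0)
    y0 = np.floor(py).astype(np.intp)
    x0 = np.floor(px).astype(np.intp)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = py - y0
    fx = px - x0
    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx

    def sample(yi, xi):
        # x.data[n, :, yi, xi] for per-batch index maps → (n, kk, h, w, c)
        ni = np.arange(n)[:, None, None, None]
        return x.data.transpose(0, 2, 3, 1)[ni, yi, xi]

    v00, v01 = sample(y0, x0), sample(y0, x1)
    v10, v11 = sample(y1, x0), sample(y1, x1)
    cols = (w00[..., None] * v00 + w01[..., None] * v01
            + w10[..., None] * v10 + w11[..., None] * v11)  # n,kk,h,w,c
    cols_mat = cols.transpose(0, 2, 3, 4, 1).reshape(n * h * w, c * kk)
    w_mat = weight.data.transpose(0, 1, 2, 3).reshape(f, c * kk)
    out = cols_mat @ w_mat.T + bias.data
    out = out.reshape(n, h, w, f).transpose(0, 3, 1, 2)

    def bwd(g):
        g_flat = g.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        if bias.requires_grad:
            bias._accum(g_flat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((g_flat.T @ cols_mat).reshape(weight.data.shape))
        dcols = (g_flat @ w_mat).reshape(n, h, w, c, kk) \
            .transpose(0, 4, 1, 2, 3)  # n,kk,h,w,c
        if x.requires_grad:
            dx = np.zeros((n, h, w, c), dtype=np.float32)
            ni = np.arange(n)[:, None, None, None]
            for yi, xi, wgt in ((y0, x0, w00), (y0, x1, w01),
                                (y1, x0, w10), (y1, x1, w11)):
                np.add.at(dx, (ni, yi, xi), dcols * wgt[..., None])
            x._accum(dx.transpose(0, 3, 1, 2))
        if offsets.requires_grad:
            dval_dy = ((v10 - v00) * (1 - fx)[..., None]
                       + (v11 - v01) * fx[..., None])
            dval_dx = ((v01 - v00) * (1 - fy)[..., None]
                       + (v11 - v10) * fy[..., None])
            doy = (dcols * dval_dy).sum(axis=-1) * inside_y
            dox = (dcols * dval_dx).sum(axis=-1) * inside_x
            doff = np.stack([doy, dox], axis=2).reshape(offsets.data.shape)
            offsets._accum(doff.astype(np.float32))

    return Tensor._make(out, (x, offsets, weight, bias), bwd)
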