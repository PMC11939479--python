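"""Neural-network layers on top of the autodiff engine.

Contains the generic layers (conv, batch norm, linear) plus the three
building blocks specific to the landmark networks: the inverted residual
block, the global depthwise convolution (GDConv) and the Semantical
Embedding Block (SEB) used by the heatmap decoder.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batch_norm, conv2d, upsample_bilinear

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU6",
    "Linear",
    "GDConv",
    "InvertedResidual",
    "SEB",
    "Adam",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval state."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v
                        yield from v.modules()

    def parameters(self):
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Parameter):
                        params.append(v)
                    elif isinstance(v, Module):
                        params.extend(v.parameters())
        return params

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _buffers(self):
        """Non-trainable state (BN running statistics), traversal order."""
        out = []
        for m in [self, *self.modules()]:
            if isinstance(m, BatchNorm2d):
                out.append(m.running_mean)
                out.append(m.running_var)
        return out

    def state_arrays(self) -> dict:
        """Parameters and buffers keyed by traversal position."""
        state = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        state.update({f"b{i}": b for i, b in enumerate(self._buffers())})
        return state

    def load_state_arrays(self, state: dict):
        """Inverse of :meth:`state_arrays` (same architecture required)."""
        params = self.parameters()
        buffers = self._buffers()
        n_p = sum(1 for k in state if k.startswith("p"))
        n_b = sum(1 for k in state if k.startswith("b"))
        if n_p != len(params) or n_b != len(buffers):
            raise ValueError("state does not match this architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(p.data.dtype)
        for i, b in enumerate(buffers):
            b[...] = np.asarray(state[f"b{i}"])


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=None, groups=1, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        if padding is None:
            padding = k // 2
        fan_in = (in_channels // groups) * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.groups = groups

    def forward(self, x):
        out = conv2d(x, self.weight, stride=self.stride,
                     padding=self.padding, groups=self.groups)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training,
                          momentum=self.momentum, eps=self.eps)


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GDConv(Module):
    """Global depthwise convolution: per-channel spatial inner product.

    The learnable kernel has the full spatial extent of the feature map.
    Initialized at 1/(h*w), i.e. exactly global average pooling, so the
    layer starts as GAP and learns position-dependent weights.
    """

    def __init__(self, channels, height, width):
        super().__init__()
        self.kernel = Parameter(
            np.full((channels, height, width), 1.0 / (height * width)))

    def forward(self, x):
        # (N,C,H,W) * (1,C,H,W) summed spatially -> (N,C)
        k = self.kernel.reshape(1, *self.kernel.shape)
        return (x * k).sum(axis=(2, 3))


class InvertedResidual(Module):
    """Expand -> dw_num depthwise 3x3 convs -> linear projection.

    The skip connection is added when stride is 1 and the channel counts
    match.  ``dw_num`` depthwise stages follow the first (strided) one at
    stride 1; each conv is followed by BN, with ReLU6 on all but the
    projection output.
    """

    def __init__(self, in_channels, out_channels, stride=1, expansion=6,
                 dw_num=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = in_channels * expansion
        self.expand = Conv2d(in_channels, hidden, 1, rng=rng)
        self.expand_bn = BatchNorm2d(hidden)
        self.dw_layers = []
        self.dw_bns = []
        for i in range(dw_num):
            self.dw_layers.append(Conv2d(hidden, hidden, 3,
                                         stride=stride if i == 0 else 1,
                                         groups=hidden, rng=rng))
            self.dw_bns.append(BatchNorm2d(hidden))
        self.project = Conv2d(hidden, out_channels, 1, rng=rng)
        self.project_bn = BatchNorm2d(out_channels)
        self.use_residual = stride == 1 and in_channels == out_channels
        self.stride = stride
        self.dw_num = dw_num
        self.expansion = expansion

    def forward(self, x):
        h = self.expand_bn(self.expand(x)).relu6()
        for conv, bn in zip(self.dw_layers, self.dw_bns):
            h = bn(conv(h)).relu6()
        h = self.project_bn(self.project(h))
        if self.use_residual:
            h = h + x
        return h


class SEB(Module):
    """Semantical Embedding Block.

    The high-level (deeper, lower-resolution) input goes through a 3x3
    conv and bilinear upsampling; the low-level input through a 1x1 conv
    and upsampling; the two are merged by elementwise multiplication at
    the common target resolution.
    """

    def __init__(self, high_channels, low_channels, out_channels, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.high_conv = Conv2d(high_channels, out_channels, 3, rng=rng)
        self.high_bn = BatchNorm2d(out_channels)
        self.low_conv = Conv2d(low_channels, out_channels, 1, rng=rng)
        self.low_bn = BatchNorm2d(out_channels)

    def forward(self, high, low, out_hw):
        h = self.high_bn(self.high_conv(high)).relu6()
        l = self.low_bn(self.low_conv(low)).relu6()
        h = upsample_bilinear(h, *out_hw)
        l = upsample_bilinear(l, *out_hw)
        return h * l


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
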