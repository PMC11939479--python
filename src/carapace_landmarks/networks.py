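"""Network architectures for the three coordinate-regression heads.

All three networks share a lightweight encoder in the MobileNetV2 /
MobileFaceNet lineage (strided first conv, inverted-residual blocks,
BN + ReLU6 everywhere except head outputs) that reduces a square input by
a fixed downsampling factor (16 at the full working resolution of 512,
giving a 128-channel 32x32 feature map):

* ``fc``   — global depthwise convolution (GDConv) over the final feature
  map plus the flattened spatial features feed a fully-connected stage
  that outputs the 78 coordinate values directly.
* ``hm``   — three Semantical Embedding Blocks (SEB) decode the encoder
  pyramid back to input resolution, one heatmap channel per landmark.
* ``dsnt`` — a 1x1 convolution maps the final feature map to one channel
  per landmark; coordinates are read out by the differentiable
  spatial-to-numerical transform.

The ``full`` preset fixes the per-block channels, expansions and depths
of the three networks; the per-block values are chosen so the trainable
parameter totals land at 0.84 M (dsnt), 0.97 M (hm) and 27.9 M (fc) at
the 512x512 working resolution.  The ``tiny`` preset is a width- and
depth-reduced variant (downsampling factor 8) for CPU-scale experiments
on small images.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import dsnt as dsnt_ops
from .nn import (SEB, BatchNorm2d, Conv2d, GDConv, InvertedResidual,
                 Linear, Module)

__all__ = [
    "IRSpec",
    "EncoderSpec",
    "NetworkSpec",
    "ResourceReport",
    "full_network_spec",
    "tiny_network_spec",
    "build_network",
    "count_parameters",
    "count_flops",
    "model_size_mb",
    "count_resources",
]


@dataclass(frozen=True)
class IRSpec:
    in_channels: int
    out_channels: int
    stride: int = 1
    expansion: int = 6
    dw_num: int = 1


@dataclass(frozen=True)
class EncoderSpec:
    conv1_channels: int
    conv1_stride: int
    blocks: tuple[IRSpec, ...]

    @property
    def downsample(self) -> int:
        f = self.conv1_stride
        for b in self.blocks:
            f *= b.stride
        return f

    @property
    def out_channels(self) -> int:
        return self.blocks[-1].out_channels


@dataclass(frozen=True)
class NetworkSpec:
    head: str                         # "fc" | "hm" | "dsnt"
    image_size: int
    n_points: int
    encoder: EncoderSpec
    fc_hidden: int = 0                # fc head only
    seb_channels: tuple[int, int, int] = (0, 0, 0)  # hm head only
    head_kernel: int = 1              # hm final conv kernel size

    @property
    def feature_size(self) -> int:
        return self.image_size // self.encoder.downsample

    def output_shape(self, image_size: int | None = None):
        """Predicted output shape for a single sample, by arithmetic."""
        s = image_size or self.image_size
        if self.head == "fc":
            return (2 * self.n_points,)
        if self.head == "hm":
            return (self.n_points, s, s)
        return (self.n_points, s // self.encoder.downsample,
                s // self.encoder.downsample)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        doc = yaml.safe_load(text)
        enc = doc.pop("encoder")
        blocks = tuple(IRSpec(**b) for b in enc.pop("blocks"))
        doc["encoder"] = EncoderSpec(blocks=blocks, **enc)
        doc["seb_channels"] = tuple(doc.get("seb_channels", (0, 0, 0)))
        return cls(**doc)


# ---------------------------------------------------------------------------
# presets


def _full_encoder() -> EncoderSpec:
    return EncoderSpec(
        conv1_channels=64, conv1_stride=2,
        blocks=(
            IRSpec(64, 64, stride=2, expansion=2, dw_num=2),
            IRSpec(64, 128, stride=2, expansion=4, dw_num=2),
            IRSpec(128, 128, stride=2, expansion=4, dw_num=2),
            IRSpec(128, 128, stride=1, expansion=6, dw_num=2),
            IRSpec(128, 128, stride=1, expansion=6, dw_num=2),
            IRSpec(128, 128, stride=1, expansion=5, dw_num=2),
        ))


def full_network_spec(head: str, n_points: int = 39) -> NetworkSpec:
    """The working-resolution (512x512) architectures."""
    if head not in ("fc", "hm", "dsnt"):
        raise ValueError(f"unknown head {head!r}")
    return NetworkSpec(
        head=head, image_size=512, n_points=n_points,
        encoder=_full_encoder(),
        fc_hidden=205 if head == "fc" else 0,
        seb_channels=(88, 24, 16) if head == "hm" else (0, 0, 0),
    )


def tiny_network_spec(head: str, image_size: int = 48,
                      n_points: int = 39) -> NetworkSpec:
    """Reduced-width networks (downsampling factor 8) for small images."""
    if head not in ("fc", "hm", "dsnt"):
        raise ValueError(f"unknown head {head!r}")
    if image_size % 8:
        raise ValueError("tiny preset requires image_size divisible by 8")
    enc = EncoderSpec(
        conv1_channels=8, conv1_stride=2,
        blocks=(
            IRSpec(8, 16, stride=2, expansion=4, dw_num=1),
            IRSpec(16, 24, stride=2, expansion=4, dw_num=1),
            IRSpec(24, 32, stride=1, expansion=4, dw_num=1),
            IRSpec(32, 32, stride=1, expansion=4, dw_num=2),
        ))
    return NetworkSpec(
        head=head, image_size=image_size, n_points=n_points, encoder=enc,
        fc_hidden=64 if head == "fc" else 0,
        seb_channels=(32, 24, 20) if head == "hm" else (0, 0, 0),
        head_kernel=3 if head == "hm" else 1,
    )


# ---------------------------------------------------------------------------
# modules


class Encoder(Module):
    """Strided conv stem + inverted-residual stack, with pyramid taps."""

    def __init__(self, spec: EncoderSpec, rng):
        super().__init__()
        self.spec = spec
        self.conv1 = Conv2d(3, spec.conv1_channels, 3,
                            stride=spec.conv1_stride, rng=rng)
        self.bn1 = BatchNorm2d(spec.conv1_channels)
        self.blocks = [InvertedResidual(b.in_channels, b.out_channels,
                                        stride=b.stride,
                                        expansion=b.expansion,
                                        dw_num=b.dw_num, rng=rng)
                       for b in spec.blocks]

    def forward(self, x):
        f1 = self.bn1(self.conv1(x)).relu6()
        taps = {"f1": f1}
        h = f1
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i == 0:
                taps["f2"] = h
            elif i == 1:
                taps["f3"] = h
        taps["f5"] = h
        return taps


class FCNet(Module):
    """Encoder + GDConv + fully-connected coordinate regression.

    The FC stage consumes the flattened final feature map concatenated
    with the GDConv global vector and emits 2*n_points values interpreted
    as normalized (x, y) pairs in schema order.  The output is a plain
    linear map (unbounded, no squashing).
    """

    def __init__(self, spec: NetworkSpec, rng):
        super().__init__()
        self.spec = spec
        self.encoder = Encoder(spec.encoder, rng)
        c = spec.encoder.out_channels
        fs = spec.feature_size
        self.gdconv = GDConv(c, fs, fs)
        self.gd_bn = BatchNorm2d(c)
        flat = c * fs * fs + c
        self.fc1 = Linear(flat, spec.fc_hidden, rng=rng)
        self.fc2 = Linear(spec.fc_hidden, 2 * spec.n_points, rng=rng)

    def forward(self, x):
        f5 = self.encoder(x)["f5"]
        g = self.gd_bn(self.gdconv(f5))
        n = f5.shape[0]
        from .autodiff import concat
        flat = concat([f5.reshape(n, -1), g], axis=1)
        return self.fc2(self.fc1(flat).relu6())


class HeatmapNet(Module):
    """Encoder + three SEB decoder stages -> one heatmap per landmark."""

    def __init__(self, spec: NetworkSpec, rng):
        super().__init__()
        self.spec = spec
        self.encoder = Encoder(spec.encoder, rng)
        enc = spec.encoder
        c1, c2, c3 = spec.seb_channels
        ch_f1 = enc.conv1_channels
        ch_f2 = enc.blocks[0].out_channels
        ch_f3 = enc.blocks[1].out_channels
        ch_f5 = enc.out_channels
        self.seb_blocks = [
            SEB(ch_f5, ch_f3, c1, rng=rng),
            SEB(c1, ch_f2, c2, rng=rng),
            SEB(c2, ch_f1, c3, rng=rng),
        ]
        self.head_conv = Conv2d(c3, spec.n_points, spec.head_kernel,
                                bias=True, rng=rng)

    def forward(self, x):
        taps = self.encoder(x)
        s = x.shape[-1]
        d = self.spec.encoder.downsample
        c1s = s // (d // 2)
        h = self.seb_blocks[0](taps["f5"], taps["f3"], (c1s, c1s))
        c2s = s // max(d // 4, 1)
        h = self.seb_blocks[1](h, taps["f2"], (c2s, c2s))
        c3s = s // max(d // 8, 1)
        h = self.seb_blocks[2](h, taps["f1"], (c3s, c3s))
        if c3s != s:
            from .autodiff import upsample_bilinear
            h = upsample_bilinear(h, s, s)
        return self.head_conv(h)


class DSNTNet(Module):
    """Encoder + 1x1 landmark-channel conv + DSNT readout.

    ``forward`` returns the raw per-landmark logits; ``forward_coords``
    additionally applies softmax normalization and the coordinate
    expectation, returning (coords, normalized heatmaps).
    """

    def __init__(self, spec: NetworkSpec, rng):
        super().__init__()
        self.spec = spec
        self.encoder = Encoder(spec.encoder, rng)
        self.head_conv = Conv2d(spec.encoder.out_channels, spec.n_points, 1,
                                bias=True, rng=rng)
        fs = spec.feature_size
        self.grids = dsnt_ops.build_grids(fs, fs)

    def forward(self, x):
        return self.head_conv(self.encoder(x)["f5"])

    def forward_coords(self, x):
        logits = self.forward(x)
        fs = logits.shape[-1]
        grids = (self.grids if fs == self.grids.shape[0]
                 else dsnt_ops.build_grids(fs, fs))
        zn = dsnt_ops.normalize_heatmaps(logits)
        coords = dsnt_ops.dsnt_expectation(zn, grids)
        return coords, zn


_HEAD_CLASSES = {"fc": FCNet, "hm": HeatmapNet, "dsnt": DSNTNet}


def build_network(spec: NetworkSpec, seed: int = 0) -> Module:
    rng = np.random.default_rng(seed)
    return _HEAD_CLASSES[spec.head](spec, rng)


# ---------------------------------------------------------------------------
# resource accounting


@dataclass
class ResourceReport:
    parameters: int
    parameters_m: float              # millions, 2 dp
    flops: float                     # one forward pass at working size
    flops_g: float
    model_size_mb: float             # serialized float32, MiB

    def as_dict(self) -> dict:
        return {"Parameters (M)": self.parameters_m,
                "FLOPs (G)": self.flops_g,
                "Model Size (MB)": round(self.model_size_mb, 2)}


def count_parameters(net: Module) -> int:
    """Number of trainable scalars (conv/linear weights, biases, BN affine)."""
    return net.n_parameters()


def _conv_flops(cin, cout, k, groups, out_hw):
    return 2.0 * (k * k * cin / groups) * cout * out_hw * out_hw


def count_flops(spec: NetworkSpec, image_size: int | None = None) -> float:
    """Forward-pass floating-point operations, counted as 2 per MAC.

    Only convolution, linear and GDConv multiply-accumulates are counted;
    BN, activations and resampling are at least two orders of magnitude
    smaller for these architectures.
    """
    s = image_size or spec.image_size
    enc = spec.encoder
    total = 0.0
    hw = s // enc.conv1_stride
    total += _conv_flops(3, enc.conv1_channels, 3, 1, hw)
    for b in enc.blocks:
        hidden = b.in_channels * b.expansion
        total += _conv_flops(b.in_channels, hidden, 1, 1, hw)
        hw = hw // b.stride
        for _ in range(b.dw_num):
            total += _conv_flops(hidden, hidden, 3, hidden, hw)
        total += _conv_flops(hidden, b.out_channels, 1, 1, hw)
    c = enc.out_channels
    fs = s // enc.downsample
    if spec.head == "fc":
        total += 2.0 * c * fs * fs                       # GDConv
        flat = c * fs * fs + c
        total += 2.0 * flat * spec.fc_hidden
        total += 2.0 * spec.fc_hidden * 2 * spec.n_points
    elif spec.head == "dsnt":
        total += _conv_flops(c, spec.n_points, 1, 1, fs)
    else:
        c1, c2, c3 = spec.seb_channels
        ch = (enc.conv1_channels, enc.blocks[0].out_channels,
              enc.blocks[1].out_channels, c)
        d = enc.downsample
        total += _conv_flops(ch[3], c1, 3, 1, fs)
        total += _conv_flops(ch[2], c1, 1, 1, s // (d // 2))
        total += _conv_flops(c1, c2, 3, 1, s // (d // 2))
        total += _conv_flops(ch[1], c2, 1, 1, s // max(d // 4, 1))
        total += _conv_flops(c2, c3, 3, 1, s // max(d // 4, 1))
        total += _conv_flops(ch[0], c3, 1, 1, s // max(d // 8, 1))
        total += _conv_flops(c3, spec.n_points, 1, 1, s)
    return total


def model_size_mb(net: Module) -> float:
    """Size of the serialized float32 parameter file, in MiB."""
    fd, path = tempfile.mkstemp(suffix=".npz")
    os.close(fd)
    try:
        np.savez(path, **net.state_arrays())
        return os.path.getsize(path) / (1024.0 * 1024.0)
    finally:
        os.unlink(path)


def count_resources(spec: NetworkSpec) -> ResourceReport:
    """Parameter, FLOP and serialized-size accounting for one spec."""
    net = build_network(spec, seed=0)
    params = count_parameters(net)
    flops = count_flops(spec)
    return ResourceReport(
        parameters=params,
        parameters_m=round(params / 1e6, 2),
        flops=flops,
        flops_g=round(flops / 1e9, 2),
        model_size_mb=model_size_mb(net),
    )
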