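"""Anchor-free rotated-stomata detection network.

The backbone is a deep-layer-aggregation (DLA) design: stages of residual
blocks fused two ways — hierarchically inside a stage (HDA, a binary tree
of blocks whose outputs meet in aggregation nodes) and iteratively across
stages (IDA, folding deeper/coarser features into shallower/finer ones).
An aggregation node is ``relu(BN(conv1x1(concat(inputs))) + x_n)`` — a
convex fusion of its inputs with a residual connection from the last one.

Four heads run on the aggregated stride-``R`` feature map (default R = 4):

* ``heatmap`` — sigmoid center-keypoint probability in (0, 1), one channel
  per class (a single "stoma" class here);
* ``size`` — long/short box axes in output-grid units (softplus, ≥ 0);
* ``offset`` — sub-cell center correction in [0, 1) (raw);
* ``angle`` — long-axis orientation, sigmoid scaled to (0, 180) degrees.

Two presets exist: ``dla_lite`` (3 shallow stages, trains on a CPU in
minutes at 256×256) and ``dla34`` (mirrors the published DLA-34 stage
layout; much heavier).  CBAM attention gates the final backbone feature;
the up-sampling projections in the IDA path can optionally be deformable
convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BasicBlock, CBAM, Conv2d, ConvBNReLU, DeformConv2d, Module,
                 Tensor, concat, upsample_bilinear2x)

_PRESETS = {
    "dla_lite": dict(stem_channels=(8,), stage_channels=(16, 32, 64),
                     stage_depths=(1, 1, 1), base_channels=16,
                     head_channels=32),
    "dla34": dict(stem_channels=(16, 32), stage_channels=(64, 128, 256, 512),
                  stage_depths=(1, 2, 2, 1), base_channels=64,
                  head_channels=256),
}


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters; ``preset`` fills the unset fields."""

    preset: str = "dla_lite"
    base_channels: int | None = None
    stage_depths: tuple[int, ...] | None = None
    stage_channels: tuple[int, ...] | None = None
    stem_channels: tuple[int, ...] | None = None
    use_attention: bool = True
    use_deformable: bool = False
    head_channels: int | None = None
    output_stride: int = 4
    num_classes: int = 1

    def resolved(self) -> "NetConfig":
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"one of {sorted(_PRESETS)}")
        merged = {k: v for k, v in _PRESETS[self.preset].items()
                  if getattr(self, k) is None}
        cfg = NetConfig(**{**self.__dict__, **merged})
        if len(cfg.stage_depths) != len(cfg.stage_channels):
            raise ValueError("stage_depths length must equal number of stages")
        # stages sit at strides 4, 8, 16, ...; the head stride must divide all
        for i in range(len(cfg.stage_channels)):
            if (4 * 2 ** i) % cfg.output_stride:
                raise ValueError("output_stride must divide every stage stride")
        return cfg

    @property
    def max_stride(self) -> int:
        n = len(self.resolved().stage_channels)
        return 2 ** (1 + n)


@dataclass
class FeatureMap:
    """Backbone feature: values (N×C×H×W tensor) and its stride vs the input."""

    values: Tensor
    stride: int


@dataclass
class HeadOutputs:
    """Per-image prediction maps at stride ``stride`` of the (padded) input."""

    heatmap: Tensor   # N×1×Hg×Wg, strictly inside (0, 1)
    size: Tensor      # N×2×Hg×Wg, output-grid units, non-negative
    offset: Tensor    # N×2×Hg×Wg
    angle: Tensor     # N×1×Hg×Wg, degrees in (0, 180)
    stride: int = 4
    input_hw: tuple[int, int] = (0, 0)  # un-padded input size


class AggregationNode(Module):
    """``relu(BN(conv1x1(concat(x_1..x_n))) + x_n)``.

    The residual runs from the last input, whose channel count must equal
    ``out_ch`` (checked at construction).
    """

    def __init__(self, rng, in_channels: list[int], out_ch: int):
        super().__init__()
        if len(in_channels) < 2:
            raise ValueError("aggregation node needs >= 2 inputs")
        if in_channels[-1] != out_ch:
            raise ValueError(
                f"residual input has {in_channels[-1]} channels, "
                f"node output has {out_ch}")
        self.in_channels = list(in_channels)
        self.conv = Conv2d(rng, sum(in_channels), out_ch, 1, padding=0,
                           bias=True)
        from .nn import BatchNorm2d
        self.bn = BatchNorm2d(out_ch)

    def forward(self, inputs: list[Tensor]) -> Tensor:
        if len(inputs) != len(self.in_channels):
            raise ValueError(f"expected {len(self.in_channels)} inputs, "
                             f"got {len(inputs)}")
        fused = self.bn(self.conv(concat(inputs, axis=1)))
        return (fused + inputs[-1]).relu()


def aggregation_node(inputs: list[FeatureMap], node: AggregationNode) -> FeatureMap:
    """Functional wrapper: aggregate same-resolution features with ``node``."""
    strides = {f.stride for f in inputs}
    if len(strides) != 1:
        raise ValueError("aggregation inputs must share a common resolution")
    return FeatureMap(node([f.values for f in inputs]), strides.pop())


class HDAStage(Module):
    """Hierarchical deep aggregation tree of depth ``depth``.

    Depth 1 aggregates two residual blocks, ``N(L1, L2)`` with
    ``L1 = B(x)`` (carrying the stage stride) and ``L2 = B(L1)``.  Deeper
    trees chain sub-trees of decreasing depth and aggregate
    ``N(R_{n-1}, …, R_1, L1, L2)``.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, depth: int,
                 stride: int = 2):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        if depth == 1:
            self.block1 = BasicBlock(rng, in_ch, out_ch, stride)
            self.block2 = BasicBlock(rng, out_ch, out_ch, 1)
            self.node = AggregationNode(rng, [out_ch, out_ch], out_ch)
            self.subtrees: list[HDAStage] = []
        else:
            self.subtrees = []
            for m in range(depth - 1, 0, -1):
                first = m == depth - 1
                self.subtrees.append(HDAStage(
                    rng, in_ch if first else out_ch, out_ch, m,
                    stride if first else 1))
            self.block1 = BasicBlock(rng, out_ch, out_ch, 1)
            self.block2 = BasicBlock(rng, out_ch, out_ch, 1)
            n_inputs = (depth - 1) + 2
            self.node = AggregationNode(rng, [out_ch] * n_inputs, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.depth == 1:
            l1 = self.block1(x)
            l2 = self.block2(l1)
            return self.node([l1, l2])
        rs = []
        cur = x
        for tree in self.subtrees:
            cur = tree(cur)
            rs.append(cur)
        l1 = self.block1(cur)
        l2 = self.block2(l1)
        return self.node(rs + [l1, l2])


hda_stage = HDAStage


def ida_combine(features: list[FeatureMap],
                nodes: list[AggregationNode] | None = None,
                up_projs: list[Module] | None = None) -> FeatureMap:
    """Iterative deep aggregation: fold deep/coarse features into shallow ones.

    ``features`` are ordered shallow→deep.  A single feature is returned
    unchanged (the recursion's base case).  Otherwise the deepest feature
    is projected (``up_projs``), up-sampled to the next-shallower stride and
    aggregated with it, iterating towards the shallowest map.  ``nodes`` and
    ``up_projs`` are ordered to match that deep→shallow walk.
    """
    if not features:
        raise ValueError("ida_combine needs at least one feature")
    if len(features) == 1:
        return features[0]
    need = len(features) - 1
    if nodes is None or len(nodes) != need or up_projs is None \
            or len(up_projs) != need:
        raise ValueError(f"need {need} aggregation nodes and projections")
    deep = features[-1]
    for i, shallow in enumerate(reversed(features[:-1])):
        up = up_projs[i](deep.values)
        ratio = deep.stride // shallow.stride
        while ratio > 1:
            up = upsample_bilinear2x(up)
            ratio //= 2
        deep = FeatureMap(nodes[i]([up, shallow.values]), shallow.stride)
    return deep


class RotatedStomataNet(Module):
    """Backbone + four prediction heads; see the module docstring."""

    def __init__(self, config: NetConfig = NetConfig(), seed: int = 0):
        super().__init__()
        cfg = config.resolved()
        self.config = cfg
        rng = np.random.default_rng(seed)

        chans = list(cfg.stage_channels)
        self.stem: list[Module] = []
        prev = 1
        for i, c in enumerate(cfg.stem_channels):
            stride = 2 if i == len(cfg.stem_channels) - 1 else 1
            self.stem.append(ConvBNReLU(rng, prev, c, 3, stride))
            prev = c
        self.stages = [
            HDAStage(rng, prev if i == 0 else chans[i - 1], c,
                     cfg.stage_depths[i], stride=2)
            for i, c in enumerate(chans)
        ]
        proj_cls = DeformConv2d if cfg.use_deformable else \
            (lambda r, ci, co: ConvBNReLU(r, ci, co, 3, 1))
        self.up_projs = [proj_cls(rng, chans[i + 1], chans[i])
                         for i in reversed(range(len(chans) - 1))]
        self.ida_nodes = [AggregationNode(rng, [chans[i], chans[i]], chans[i])
                          for i in reversed(range(len(chans) - 1))]
        self.attention = CBAM(rng, chans[0]) if cfg.use_attention else None

        def head(out_ch: int, bias_init: float) -> list[Module]:
            return [Conv2d(rng, chans[0], cfg.head_channels, 3),
                    Conv2d(rng, cfg.head_channels, out_ch, 1, padding=0,
                           bias_init=bias_init)]

        self.head_heatmap = head(cfg.num_classes, -2.19)  # sigmoid ≈ 0.1
        self.head_size = head(2, 10.0)                    # softplus ≈ 10 cells
        self.head_offset = head(2, 0.0)
        self.head_angle = head(1, 0.0)                    # sigmoid·180 = 90°

    # -- forward -----------------------------------------------------------

    def _prepare(self, images) -> tuple[Tensor, tuple[int, int]]:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        n, c, h, w = arr.shape
        if c != 1:
            raise ValueError("expected single-channel (grayscale) input")
        s = self.config.max_stride
        ph, pw = (-h) % s, (-w) % s
        if ph or pw:
            arr = np.pad(arr, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return Tensor(arr / 127.5 - 1.0), (h, w)

    def backbone(self, x: Tensor) -> FeatureMap:
        for layer in self.stem:
            x = layer(x)
        feats: list[FeatureMap] = []
        stride = 2
        for stage in self.stages:
            stride *= 2
            x = stage(x)
            feats.append(FeatureMap(x, stride))
        fused = ida_combine(feats, self.ida_nodes, self.up_projs)
        if self.attention is not None:
            fused = FeatureMap(self.attention(fused.values), fused.stride)
        return fused

    def _run_head(self, layers: list[Module], x: Tensor) -> Tensor:
        return layers[1](layers[0](x).relu())

    def forward(self, images) -> HeadOutputs:
        x, input_hw = self._prepare(images)
        feat = self.backbone(x)
        raw_heat = self._run_head(self.head_heatmap, feat.values)
        heat = raw_heat.sigmoid().clip(1e-4, 1.0 - 1e-4)
        size = self._run_head(self.head_size, feat.values).softplus()
        offset = self._run_head(self.head_offset, feat.values)
        angle = self._run_head(self.head_angle, feat.values).sigmoid() * 180.0
        for name, t in (("heatmap", heat), ("size", size),
                        ("offset", offset), ("angle", angle)):
            if not np.isfinite(t.data).all():
                raise RuntimeError(f"non-finite values in {name} head")
        assert feat.stride == self.config.output_stride
        return HeadOutputs(heat, size, offset, angle, feat.stride, input_hw)
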