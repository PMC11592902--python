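"""Compact EfficientNetV2-style convolutional feature extractor.

Stages are sequences of Fused-MBConv blocks (3x3 expansion conv + 1x1
projection, fused) followed by MBConv blocks (1x1 expansion, 3x3 depthwise,
1x1 projection), each with SiLU activations and residual connections where
stride and channel counts allow.  An optional per-stage "supporter" insert
adds a squeeze-and-recalibration path (global average pool -> bottleneck MLP
-> sigmoid gate on channels), the channel-attention reading of a supporter
block living inside the conv stages.

No pretrained weights exist for this model family here; the default config
is a three-stage, sub-200k-parameter variant sized for desk-scale training.
Initialisation is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["StageConfig", "BackboneConfig", "Backbone", "build_backbone",
           "extract_features"]


@dataclass(frozen=True)
class StageConfig:
    block_type: str  # "fused_mbconv" | "mbconv"
    repeats: int = 1
    channels: int = 8
    stride: int = 2
    expansion: int = 2

    def __post_init__(self):
        if self.block_type not in ("fused_mbconv", "mbconv"):
            raise ValueError(f"unknown block type {self.block_type!r}")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.channels <= 0 or self.repeats <= 0 or self.expansion <= 0:
            raise ValueError("channels, repeats and expansion must be positive")


def default_stages() -> tuple[StageConfig, ...]:
    return (
        StageConfig("fused_mbconv", 1, 8, 2, 1),
        StageConfig("fused_mbconv", 1, 16, 2, 2),
        StageConfig("mbconv", 1, 16, 2, 2),
    )


@dataclass(frozen=True)
class BackboneConfig:
    stages: tuple[StageConfig, ...] = field(default_factory=default_stages)
    in_channels: int = 1
    input_size: tuple[int, int] = (32, 32)
    supporter_insertion: tuple[bool, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        s = self.stride_product
        if h % s or w % s:
            raise ValueError(
                f"input size {self.input_size} not divisible by stride product {s}"
            )
        if self.supporter_insertion is not None and \
                len(self.supporter_insertion) != len(self.stages):
            raise ValueError("supporter_insertion must have one flag per stage")

    @property
    def stride_product(self) -> int:
        return int(np.prod([s.stride for s in self.stages]))

    @property
    def out_channels(self) -> int:
        return self.stages[-1].channels

    def out_spatial(self) -> tuple[int, int]:
        h, w = self.input_size
        s = self.stride_product
        return h // s, w // s


class SqueezeRecalibrate(nn.Module):
    """Channel gate: GAP -> bottleneck MLP -> sigmoid, multiplied back in."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))          # (N, C)
        gate = self.fc2(self.fc1(pooled).silu()).sigmoid()
        n, c = gate.shape
        return x * gate.reshape(n, c, 1, 1)


class FusedMBConv(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int, expansion: int,
                 rng: np.random.Generator, recalibrate: bool):
        if expansion > 1:
            mid = cin * expansion
            self.expand = nn.Conv2d(cin, mid, 3, rng, stride=stride)
            self.project = nn.Conv2d(mid, cout, 1, rng)
        else:  # fused block degenerates to a single 3x3 conv
            self.expand = nn.Conv2d(cin, cout, 3, rng, stride=stride)
            self.project = None
        self.gate = SqueezeRecalibrate(cout, rng) if recalibrate else None
        self.residual = stride == 1 and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        out = self.expand(x).silu()
        if self.project is not None:
            out = self.project(out)
        if self.gate is not None:
            out = self.gate(out)
        if self.residual:
            out = out + x
        return out


class MBConv(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int, expansion: int,
                 rng: np.random.Generator, recalibrate: bool):
        mid = cin * expansion
        self.expand = nn.Conv2d(cin, mid, 1, rng)
        self.depthwise = nn.DepthwiseConv2d(mid, 3, rng, stride=stride)
        self.project = nn.Conv2d(mid, cout, 1, rng)
        self.gate = SqueezeRecalibrate(cout, rng) if recalibrate else None
        self.residual = stride == 1 and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        out = self.expand(x).silu()
        out = self.depthwise(out).silu()
        out = self.project(out)
        if self.gate is not None:
            out = self.gate(out)
        if self.residual:
            out = out + x
        return out


class Backbone(nn.Module):
    """Feature extractor returning the final map and per-stage outputs."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        flags = config.supporter_insertion or (False,) * len(config.stages)
        blocks: list[nn.Module] = []
        self.stage_slices: list[tuple[int, int]] = []
        cin = config.in_channels
        for stage, flag in zip(config.stages, flags):
            start = len(blocks)
            for r in range(stage.repeats):
                stride = stage.stride if r == 0 else 1
                cls = FusedMBConv if stage.block_type == "fused_mbconv" else MBConv
                blocks.append(cls(cin, stage.channels, stride, stage.expansion,
                                  rng, recalibrate=flag))
                cin = stage.channels
            self.stage_slices.append((start, len(blocks)))
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        fmap, _ = self.forward_with_stages(x)
        return fmap

    def forward_with_stages(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Run the stages; also return each stage's output map."""
        n, c, h, w = x.shape
        eh, ew = self.config.input_size
        if (c, h, w) != (self.config.in_channels, eh, ew):
            raise ValueError(
                f"input shape {(c, h, w)} does not match config "
                f"{(self.config.in_channels, eh, ew)}"
            )
        stage_outputs: list[Tensor] = []
        out = x
        for start, end in self.stage_slices:
            for b in self.blocks[start:end]:
                out = b(out)
            stage_outputs.append(out)
        return out, stage_outputs


def build_backbone(config: BackboneConfig) -> Backbone:
    """Construct a backbone; raises on stride/size mismatch (in the config)."""
    return Backbone(config)


def extract_features(extractor: Backbone, batch: np.ndarray | Tensor) -> Tensor:
    """Feature maps for a batch of preprocessed (N, C, H, W) images."""
    x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch))
    out = extractor(x)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("non-finite values in extracted features")
    return out
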