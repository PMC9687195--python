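"""Convolutional branch: a ResNet50-style stem and four bottleneck stages.

The stem is a 7×7 stride-2 convolution + batch normalization + ReLU + 3×3
stride-2 max pooling (1/4 resolution, 64 channels by default). Each stage is
a stack of v1 bottleneck residual blocks (1×1 reduce → 3×3 → 1×1 expand with
a projection shortcut on the first block); stage 1 keeps resolution, stages
2–4 halve it, so for a 224 input the stage maps are
56×56/256 → 28×28/512 → 14×14/1024 → 7×7/2048 — resolution-matched to the
Transformer branch at every stage, which the fusion module requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor

__all__ = ["CNNStageConfig", "Bottleneck", "CNNBranch"]


@dataclass(frozen=True)
class CNNStageConfig:
    """Channel/block plan for the convolutional branch."""

    channels: tuple = (256, 512, 1024, 2048)
    blocks: tuple = (3, 4, 6, 3)
    stem_channels: int = 64

    @classmethod
    def resnet50(cls) -> "CNNStageConfig":
        return cls()

    @classmethod
    def tiny(cls) -> "CNNStageConfig":
        """Desk-scale plan: one block per stage, narrow channels."""
        return cls(channels=(32, 64, 128, 256), blocks=(1, 1, 1, 1), stem_channels=16)


class Bottleneck(nn.Module):
    """1×1 reduce → 3×3 → 1×1 expand, BN after each conv, residual add, ReLU."""

    EXPANSION = 4

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, *, rng):
        super().__init__()
        mid = out_ch // self.EXPANSION
        self.conv1 = nn.Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x
        if self.down_conv is not None:
            shortcut = self.down_bn(self.down_conv(x))
        return (out + shortcut).relu()


class CNNBranch(nn.Module):
    def __init__(self, config: CNNStageConfig | None = None, *, rng=None):
        super().__init__()
        if config is None:
            config = CNNStageConfig.resnet50()
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        c0 = config.stem_channels
        self.stem_conv = nn.Conv2d(3, c0, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c0)
        self.stem_pool = nn.MaxPool2d(3, 2, 1)

        stages = []
        in_ch = c0
        for i, (out_ch, n_blocks) in enumerate(zip(config.channels, config.blocks)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (i > 0 and b == 0) else 1
                blocks.append(Bottleneck(in_ch, out_ch, stride, rng=rng))
                in_ch = out_ch
            stages.append(nn.ModuleList(blocks))
        self.stage_list = nn.ModuleList(stages)

    def stem(self, image: Tensor) -> Tensor:
        """3-channel input → stem_channels map at 1/4 resolution, values ≥ 0."""
        if image.shape[1] != 3:
            raise ValueError(f"stem expects 3-channel input, got {image.shape[1]}")
        return self.stem_pool(self.stem_bn(self.stem_conv(image)).relu())

    def stage_forward(self, index: int, x: Tensor) -> Tensor:
        """Run stage ``index`` (0-based); accepts externally injected (fused)
        maps as long as the channel count matches the plan."""
        expected = self.config.stem_channels if index == 0 else self.config.channels[index - 1]
        if x.shape[1] != expected:
            raise ValueError(
                f"stage {index + 1} expects {expected} input channels, got {x.shape[1]}"
            )
        for blk in self.stage_list[index]:
            x = blk(x)
        return x

    def forward(self, image: Tensor) -> list[Tensor]:
        x = self.stem(image)
        maps = []
        for i in range(len(self.stage_list)):
            x = self.stage_forward(i, x)
            maps.append(x)
        return maps
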