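"""The denoising network: a four-level U-Net built from residual dense
connectivity blocks (RDCBs).

Topology
--------
A 3x3 stem lifts the single input channel to the first width of the channel
plan (default 128).  Four encoder levels follow, each being two RDCBs, a 2x2
max-pool, and a 1x1 conv+BN+ReLU that sets the next level's width
(128 -> 256 -> 512 -> 1024 -> 1024); the bottleneck applies two further RDCBs
at 1/16 scale.  Four decoder levels mirror this: a 3x3 conv doubles the
channels, a factor-2 pixel shuffle trades them for resolution (half the input
channels at twice the size), the result is concatenated with the matching
encoder skip, fused by a 1x1 conv+BN+ReLU back to the level's width, and
refined by two RDCBs.  A bias-only 1x1 head projects to one channel with no
activation; clipping to the intensity range happens only at image export.

An RDCB is three conv+BN+ReLU stages with dense connectivity (each stage sees
the concatenation of the block input and all previous stage outputs), a 1x1
projection back to the block width, and a local residual addition of the block
input.  Setting ``dense_connectivity=False`` chains the stages instead
(each sees only its predecessor), the ablation of the dense wiring.

Odd spatial sizes are handled by reflection-padding one pixel before a pool
and cropping back after the corresponding pixel shuffle, so any input of at
least 16 px per side round-trips at its own size (including 40x40 training
patches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .image import GrayImage
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["RDCBConfig", "GeneratorConfig", "RDCB", "EncoderLevel", "DecoderLevel", "DenoisingUNet", "denoise_image"]

MIN_SIDE = 16  # four halvings from here still leave a 1-px bottleneck


@dataclass(frozen=True)
class RDCBConfig:
    """Shape contract of one residual dense connectivity block."""

    channels: int
    n_convs: int = 3
    dense_connectivity: bool = True

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.n_convs != 3:
            raise ValueError("the block uses exactly three conv stages")


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture hyperparameters of the denoising U-Net."""

    in_channels: int = 1
    channel_plan: tuple[int, int, int, int] = (128, 256, 512, 1024)
    rdcb_per_block: int = 2
    dense_connectivity: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.in_channels != 1:
            raise ValueError("the denoiser is single-channel")
        if len(self.channel_plan) != 4 or any(c < 4 for c in self.channel_plan):
            raise ValueError("channel_plan must list four widths >= 4")
        if any(c % 4 for c in self.channel_plan):
            raise ValueError("channel widths must be divisible by 4 (pixel shuffle)")

    @classmethod
    def scaled(cls, divisor: int, **kwargs) -> "GeneratorConfig":
        """A topology-preserving shrink of the default plan for desk-scale runs."""
        plan = tuple(max(c // divisor, 4) for c in (128, 256, 512, 1024))
        return cls(channel_plan=plan, **kwargs)  # type: ignore[arg-type]

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class RDCB(nn.Module):
    """Residual dense connectivity block; shape- and channel-preserving."""

    def __init__(self, config: RDCBConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        c = config.channels
        self.config = config
        if config.dense_connectivity:
            ins = (c, 2 * c, 3 * c)
            proj_in = 4 * c
        else:
            ins = (c, c, c)
            proj_in = c
        self.stages = [nn.ConvBNReLU(i, c, 3, padding=1, rng=rng, dtype=dtype) for i in ins]
        self.proj = nn.Conv2d(proj_in, c, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.config.channels:
            raise ValueError(f"RDCB expects {self.config.channels} channels, got {x.shape[-1]}")
        feats = [x]
        for stage in self.stages:
            inp = ag.concat(feats) if self.config.dense_connectivity and len(feats) > 1 else feats[-1]
            feats.append(stage(inp))
        proj_in = ag.concat(feats) if self.config.dense_connectivity else feats[-1]
        return ag.add(self.proj(proj_in), x)


class EncoderLevel(nn.Module):
    """Two RDCBs -> 2x2 max-pool -> 1x1 conv+BN+ReLU widening to the next level.

    Returns ``(pooled, skip)`` where ``skip`` is the pre-pool feature map used
    by the matching decoder level.
    """

    def __init__(self, channels: int, out_channels: int, config: GeneratorConfig, rng, dtype):
        super().__init__()
        block = RDCBConfig(channels, dense_connectivity=config.dense_connectivity)
        self.rdcbs = [RDCB(block, rng, dtype) for _ in range(config.rdcb_per_block)]
        self.transition = nn.ConvBNReLU(channels, out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        for block in self.rdcbs:
            x = block(x)
        skip = x
        h, w = x.shape[1], x.shape[2]
        x = ag.pad_bottom_right_reflect(x, h % 2, w % 2)
        x = ag.maxpool2x2(x)
        return self.transition(x), skip


class DecoderLevel(nn.Module):
    """3x3 conv doubling channels -> pixel shuffle -> skip concat -> 1x1 fuse -> two RDCBs."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int, config: GeneratorConfig, rng, dtype):
        super().__init__()
        self.upconv = nn.Conv2d(in_channels, 2 * in_channels, 3, padding=1, bias=True, rng=rng, dtype=dtype)
        self.fuse = nn.ConvBNReLU(in_channels // 2 + skip_channels, out_channels, 1, rng=rng, dtype=dtype)
        block = RDCBConfig(out_channels, dense_connectivity=config.dense_connectivity)
        self.rdcbs = [RDCB(block, rng, dtype) for _ in range(config.rdcb_per_block)]

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = ag.pixel_shuffle2(self.upconv(x))
        sh, sw = skip.shape[1], skip.shape[2]
        if x.shape[1] < sh or x.shape[2] < sw:
            raise ValueError(f"upsampled map {x.shape[1]}x{x.shape[2]} smaller than skip {sh}x{sw}")
        x = ag.crop(x, sh, sw)
        x = self.fuse(ag.concat([x, skip]))
        for block in self.rdcbs:
            x = block(x)
        return x


class DenoisingUNet(nn.Module):
    """Noisy grayscale image in, denoised estimate of identical size out."""

    def __init__(self, config: GeneratorConfig = GeneratorConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        dtype = config.np_dtype
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6E0D]))
        plan = config.channel_plan
        self.stem = nn.ConvBNReLU(config.in_channels, plan[0], 3, padding=1, rng=rng, dtype=dtype)
        next_ch = (plan[1], plan[2], plan[3], plan[3])
        self.encoders = [
            EncoderLevel(plan[i], next_ch[i], config, rng, dtype) for i in range(4)
        ]
        bottleneck_cfg = RDCBConfig(plan[3], dense_connectivity=config.dense_connectivity)
        self.bottleneck = [RDCB(bottleneck_cfg, rng, dtype) for _ in range(config.rdcb_per_block)]
        dec_in = (plan[1], plan[2], plan[3], plan[3])  # indexed by level 0..3
        self.decoders = [
            DecoderLevel(dec_in[i], plan[i], plan[i], config, rng, dtype) for i in range(4)
        ]
        self.head = nn.Conv2d(plan[0], 1, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels}-channel input, got {c}")
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValueError(
                f"input {h}x{w} is below the {MIN_SIDE}px minimum; pad to at least "
                f"{max(h, MIN_SIDE)}x{max(w, MIN_SIDE)}"
            )
        x = self.stem(x)
        skips: list[Tensor] = []
        for enc in self.encoders:
            x, skip = enc(x)
            skips.append(skip)
        for block in self.bottleneck:
            x = block(x)
        for level in (3, 2, 1, 0):
            x = self.decoders[level](x, skips[level])
        return self.head(x)


def denoise_image(net: DenoisingUNet, image: GrayImage) -> GrayImage:
    """Run the network on one image in evaluation mode (running BN statistics)."""
    net.eval()
    unit = image.to_unit()
    x = Tensor(unit.pixels.astype(net.config.np_dtype)[None, :, :, None])
    y = net(x)
    out = GrayImage(np.asarray(y.data[0, :, :, 0], dtype=np.float64), unit.scale)
    return out if image.scale == unit.scale else out.to_eight_bit()
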