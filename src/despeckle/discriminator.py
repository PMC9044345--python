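"""The adversarial critic: a stack of convolutions scoring clean vs denoised.

Ten 3x3 convolutions arranged as five blocks of (stride-1 conv, stride-2 conv)
so each block halves the spatial dims; block output widths follow the plan
(64, 128, 256, 512, 1).  The input conv and the final 1-channel logit conv
carry biases and no BN/ReLU (a ReLU on the logit layer would pin the scores
nonnegative; the critic must emit unbounded logits for the logit-domain binary
cross-entropy); the eight interior convs are conv+BN+ReLU.  Odd sizes halve
with floor semantics via one-sided zero padding, e.g. 40 -> 20 -> 10 -> 5 ->
2 -> 1.  The decision is patch-style: a 1-channel logit map plus its spatial
mean as the scalar summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["DiscriminatorConfig", "PatchCritic"]


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 1
    channel_plan: tuple[int, int, int, int, int] = (64, 128, 256, 512, 1)
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.channel_plan[-1] != 1:
            raise ValueError("the final block must emit exactly 1 logit channel")
        if len(self.channel_plan) != 5:
            raise ValueError("channel_plan must list five block widths")

    @classmethod
    def scaled(cls, divisor: int, **kwargs) -> "DiscriminatorConfig":
        plan = tuple(max(c // divisor, 4) for c in (64, 128, 256, 512)) + (1,)
        return cls(channel_plan=plan, **kwargs)  # type: ignore[arg-type]

    @property
    def n_blocks(self) -> int:
        return len(self.channel_plan)

    @property
    def min_input(self) -> int:
        return 2 ** self.n_blocks

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


# one-sided (top/left) zero padding makes the stride-2 3x3 conv halve with
# floor semantics for any size >= 2
_STRIDE2_PAD = (1, 0, 1, 0)


class PatchCritic(nn.Module):
    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        dtype = config.np_dtype
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xD15C]))
        plan = config.channel_plan
        layers: list[nn.Module] = []
        prev = config.in_channels
        for i, width in enumerate(plan):
            last = i == len(plan) - 1
            inner = prev if last else width  # final block keeps its width until the logit conv
            if i == 0:  # input conv: bias, no BN
                layers.append(nn.Conv2d(prev, inner, 3, padding=1, bias=True, rng=rng, dtype=dtype))
            else:
                layers.append(nn.ConvBNReLU(prev, inner, 3, padding=1, rng=rng, dtype=dtype))
            if last:  # logit conv: bias, no BN/ReLU, unbounded output
                layers.append(
                    nn.Conv2d(inner, width, 3, stride=2, padding=_STRIDE2_PAD, bias=True, rng=rng, dtype=dtype)
                )
            else:
                layers.append(
                    nn.ConvBNReLU(inner, width, 3, stride=2, padding=_STRIDE2_PAD, rng=rng, dtype=dtype)
                )
            prev = width
        self.layers = layers

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return ``(logit_map, scalar_logit)``; the scalar is the map's mean."""
        n, h, w, c = x.shape
        if min(h, w) < self.config.min_input:
            raise ValueError(
                f"input {h}x{w} smaller than the critic's total downsampling factor {self.config.min_input}"
            )
        out = ag.relu(self.layers[0](x))
        for layer in self.layers[1:]:
            out = layer(out)
        return out, ag.mean(out)
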