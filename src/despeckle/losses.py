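"""The weighted joint objective: pixel L1 + perceptual distance + adversarial BCE.

The total loss is ``lambda1 * L1 + lambda2 * Lper + lambda3 * L_BCE`` with
defaults (1, 0.1, 1).  ``L1`` is the sum of absolute pixel differences (a
mean-reduced variant exists for batch-size-invariant logging), ``Lper`` is the
raw squared Euclidean distance between frozen feature-extractor responses,
and the adversarial terms are numerically stable binary cross-entropies on
raw logits.

Feature extractors are pure frozen functions.  The reference backend is the
slice of a pretrained VGG-19 up to (excluding) the first pooling layer; since
its weights are a multi-hundred-MB download, the package also ships a seeded
random convnet of the same topology whose fixed He-initialized weights make
the perceptual distance a valid (if untrained) structural metric — random
shallow conv features are a long-standing stand-in in perceptual-metric
studies, and they keep the whole test suite offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import GrayImage
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "LossWeights",
    "FeatureExtractor",
    "IdentityFeatures",
    "RandomConvFeatures",
    "create_extractor",
    "l1_loss",
    "perceptual_loss",
    "adversarial_losses",
    "discriminator_loss",
    "generator_adversarial_loss",
    "joint_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the joint objective."""

    lambda1: float = 1.0
    lambda2: float = 0.1
    lambda3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, GrayImage):
        return Tensor(x.pixels)
    return Tensor(np.asarray(x))


class FeatureExtractor:
    """A frozen mapping from images to feature maps (pure function)."""

    identifier: str = "base"
    in_channels: int = 1

    def __call__(self, x: Tensor) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def adapt_channels(self, x: Tensor) -> Tensor:
        c = x.shape[-1]
        if c == self.in_channels:
            return x
        if c == 1 and self.in_channels == 3:
            return ag.concat([x, x, x], axis=-1)
        raise ValueError(f"{self.identifier} expects {self.in_channels} channels, got {c}")


class IdentityFeatures(FeatureExtractor):
    """theta = id; reduces the perceptual loss to the squared pixel L2 distance."""

    identifier = "identity"

    def __call__(self, x: Tensor) -> Tensor:
        return x


class RandomConvFeatures(FeatureExtractor):
    """Seeded frozen two-conv ReLU net mirroring the VGG-19 pre-pool1 slice."""

    identifier = "random_convnet"

    def __init__(self, channels: int = 32, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xFEA7]))

        def he(shape):  # (kh, kw, in, out)
            fan_in = shape[0] * shape[1] * shape[2]
            w = rng.standard_normal(shape, dtype=np.float32) * np.sqrt(2.0 / fan_in)
            return Tensor(w.astype(dtype))

        self.w1 = he((3, 3, 1, channels))
        self.w2 = he((3, 3, channels, channels))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.adapt_channels(x)
        x = ag.relu(ag.conv2d(x, self.w1, padding=1))
        return ag.relu(ag.conv2d(x, self.w2, padding=1))


class VGGFirstBlockFeatures(FeatureExtractor):
    """Pretrained VGG-19 conv1_1/conv1_2 slice (output before the first pooling).

    Requires a local ``.npz`` with arrays ``conv1_1_w``, ``conv1_1_b``,
    ``conv1_2_w``, ``conv1_2_b`` exported from the torchvision weights.
    """

    identifier = "vgg19_pre_pool1"
    in_channels = 3

    def __init__(self, weights_path: str | Path):
        with np.load(Path(weights_path)) as data:
            self.w1 = Tensor(data["conv1_1_w"].astype(np.float32))
            self.b1 = Tensor(data["conv1_1_b"].astype(np.float32))
            self.w2 = Tensor(data["conv1_2_w"].astype(np.float32))
            self.b2 = Tensor(data["conv1_2_b"].astype(np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.adapt_channels(x)
        x = ag.relu(ag.conv2d(x, self.w1, self.b1, padding=1))
        return ag.relu(ag.conv2d(x, self.w2, self.b2, padding=1))


def create_extractor(
    identifier: str,
    *,
    weights_path: str | Path | None = None,
    seed: int = 0,
    channels: int = 32,
) -> FeatureExtractor:
    if identifier == "identity":
        return IdentityFeatures()
    if identifier == "random_convnet":
        return RandomConvFeatures(channels=channels, seed=seed)
    if identifier == "vgg19_pre_pool1":
        if weights_path is None or not Path(weights_path).exists():
            raise FileNotFoundError(
                "the vgg19_pre_pool1 backend needs a local weight file (pretrained weights "
                "are not bundled); pass --perceptual-backend random_convnet to use the "
                "seeded offline extractor instead"
            )
        return VGGFirstBlockFeatures(weights_path)
    raise ValueError(f"unknown perceptual backend {identifier!r}")


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def l1_loss(denoised, reference, reduction: str = "sum"):
    """Sum (or mean) of absolute pixel differences.

    The sum is the formula's literal reading; ``reduction='mean'`` divides by
    the element count for batch-size-invariant reporting.  Returns a Tensor if
    either input is one (so gradients flow), else a float.
    """
    x, y = _as_tensor(denoised), _as_tensor(reference)
    _check_same_shape(x, y)
    out = ag.l1_sum(x, y)
    if reduction == "mean":
        out = out * (1.0 / x.data.size)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    if isinstance(denoised, Tensor) or isinstance(reference, Tensor):
        return out
    return out.item()


def perceptual_loss(reference, denoised, extractor: FeatureExtractor, reduction: str = "sum"):
    """Squared Euclidean norm of the feature-map difference theta(ref) - theta(out)."""
    x, y = _as_tensor(reference), _as_tensor(denoised)
    _check_same_shape(x, y)
    if x.data.ndim == 2:  # plain 2-D images: value-only path (gradients need NHWC tensors)
        x, y = Tensor(x.data[None, :, :, None]), Tensor(y.data[None, :, :, None])
    fx, fy = extractor(x), extractor(y)
    out = ag.squared_error_sum(fx, fy)
    if reduction == "mean":
        out = out * (1.0 / fx.data.size)
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    if isinstance(reference, Tensor) or isinstance(denoised, Tensor):
        return out
    return out.item()


def discriminator_loss(real_logits, fake_logits):
    """BCE(real, 1) + BCE(fake, 0); fake logits should be detached upstream."""
    return ag.bce_with_logits_mean(_as_tensor(real_logits), 1.0) + ag.bce_with_logits_mean(
        _as_tensor(fake_logits), 0.0
    )


def generator_adversarial_loss(fake_logits):
    """BCE(fake, 1): the generator is rewarded for fooling the critic."""
    return ag.bce_with_logits_mean(_as_tensor(fake_logits), 1.0)


def adversarial_losses(real_logits, fake_logits):
    """Return ``(discriminator_loss, generator_adversarial_loss)`` on the given logits."""
    d = discriminator_loss(real_logits, fake_logits)
    g = generator_adversarial_loss(fake_logits)
    if isinstance(real_logits, Tensor) or isinstance(fake_logits, Tensor):
        return d, g
    return d.item(), g.item()


def joint_loss(l1, lper, lbce, weights: LossWeights = LossWeights()):
    """The weighted combination lambda1*L1 + lambda2*Lper + lambda3*L_BCE."""
    comps = (l1, lper, lbce)
    for name, c in zip(("l1", "lper", "lbce"), comps):
        val = c.item() if isinstance(c, Tensor) else float(c)
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"loss component {name} must be finite and >= 0, got {val}")
    if any(isinstance(c, Tensor) for c in comps):
        terms = [_as_tensor(c) * w for c, w in zip(comps, (weights.lambda1, weights.lambda2, weights.lambda3))]
        return terms[0] + terms[1] + terms[2]
    return weights.lambda1 * float(l1) + weights.lambda2 * float(lper) + weights.lambda3 * float(lbce)
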