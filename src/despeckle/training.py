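"""Adversarial training loop for the denoiser.

Each step draws a batch of random clean patches, applies one of the eight
dihedral symmetries per patch, corrupts the clean patch with fresh speckle,
and then alternates: the critic is updated on (clean, detached denoised)
pairs with targets 1/0, after which the generator is updated on the weighted
joint objective (pixel L1 + perceptual distance + adversarial BCE against
the freshly updated critic).  An epoch is one sampled patch per training
image.  The learning rate halves every ``lr_halving_period`` epochs.

Runs are repeated ``repeats`` times from derived seeds; every repeat is kept
so that evaluation can report mean +/- standard deviation across repeats.
The whole loop is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .discriminator import DiscriminatorConfig, PatchCritic
from .generator import DenoisingUNet, GeneratorConfig
from .image import GrayImage, Scale
from .losses import (
    LossWeights,
    create_extractor,
    discriminator_loss,
    generator_adversarial_loss,
    joint_loss,
    l1_loss,
    perceptual_loss,
)
from .nn import Adam, trim_heap
from .nn.autograd import Tensor
from .noise import SpeckleParams, add_speckle

__all__ = [
    "TrainConfig",
    "TrainResult",
    "dihedral_transform",
    "dihedral_inverse",
    "extract_patches",
    "lr_schedule",
    "train",
    "train_repeats",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (defaults follow the study protocol)."""

    patch_size: int = 40
    batch_size: int = 32
    base_lr: float = 1e-4
    lr_halving_period: int = 2000
    epochs: int = 8000
    sigma_8bit: float = 25.0
    noise_exponent: float = 0.5
    augmentation: bool = True
    seed: int = 0
    repeats: int = 3
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    perceptual_backend: str = "random_convnet"
    perceptual_channels: int = 32

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.batch_size < 1:
            raise ValueError("patch_size and batch_size must be >= 1")
        if self.perceptual_channels < 1:
            raise ValueError("perceptual_channels must be >= 1")
        if self.base_lr <= 0 or not np.isfinite(self.base_lr):
            raise ValueError("base_lr must be positive and finite")
        if self.lr_halving_period < 1:
            raise ValueError("lr_halving_period must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.sigma_8bit < 0:
            raise ValueError("sigma_8bit must be >= 0")

    @classmethod
    def smoke(cls, *, sigma_8bit: float = 25.0, epochs: int = 5, seed: int = 0, **kwargs) -> "TrainConfig":
        """The desk-scale profile: full-frame 64px patches, batch 4, 1/8-width nets.

        Topology (levels, block wiring, loss weights, optimizer family) is
        identical to the full profile; every network — generator, critic and
        the random perceptual extractor — is scaled down by the same factor
        of 8.  Patches cover the whole 64px phantom frame so that training
        and evaluation see the same bottleneck geometry (a multi-scale net
        trained at one input size does not transfer to another; see the
        repository notes).  The lr halving period is compressed so the short
        run performs the same number of halvings as the full protocol
        (without decay, Adam on the sign gradients of L1 oscillates around
        the optimum with amplitude set by the lr and never converges).
        """
        return cls(
            patch_size=64,
            batch_size=4,
            base_lr=1e-3,
            # ~5 halvings across the run, whatever its length, mirroring the
            # full profile's schedule compressed into the short budget
            lr_halving_period=max(1, epochs // 5),
            epochs=epochs,
            sigma_8bit=sigma_8bit,
            seed=seed,
            generator=GeneratorConfig.scaled(8),
            discriminator=DiscriminatorConfig.scaled(8),
            perceptual_channels=4,
            **kwargs,
        )


@dataclass
class TrainResult:
    """One completed run: final networks plus the per-epoch loss history."""

    generator: DenoisingUNet
    critic: PatchCritic
    history: list[dict]
    config: TrainConfig
    repeat_index: int


def dihedral_transform(arr: np.ndarray, k: int) -> np.ndarray:
    """Apply element ``k`` (0..7) of the dihedral group D4 to the last-but-one axes.

    ``k`` in 0..3 rotates by 90k degrees; ``k`` in 4..7 mirrors left-right first.
    Odd rotations of non-square arrays are rejected rather than silently reshaped.
    """
    if not 0 <= k <= 7:
        raise ValueError(f"dihedral index must be in 0..7, got {k}")
    h, w = arr.shape[-2], arr.shape[-1]
    rot = k % 4
    if rot % 2 == 1 and h != w:
        raise ValueError(f"90-degree rotation of a non-square {h}x{w} patch is undefined")
    out = arr[..., :, ::-1] if k >= 4 else arr
    return np.ascontiguousarray(np.rot90(out, rot, axes=(-2, -1)))


def dihedral_inverse(k: int) -> int:
    """Index of the inverse transform: applying ``k`` then ``dihedral_inverse(k)`` is the identity."""
    if not 0 <= k <= 7:
        raise ValueError(f"dihedral index must be in 0..7, got {k}")
    if k < 4:
        return (-k) % 4
    return k  # every reflection is its own inverse


def extract_patches(
    images: list[GrayImage],
    patch_size: int,
    rng: np.random.Generator,
    *,
    return_origins: bool = False,
):
    """One uniformly placed square crop per image, stacked as ``(N, p, p)``.

    Images smaller than the patch in either dimension are skipped with a
    warning; an all-skipped dataset is an error.  All images must be on the
    unit scale (training operates there exclusively).
    """
    patches, origins = [], []
    skipped = 0
    for img in images:
        if img.scale != Scale.UNIT:
            raise ValueError("training patches must come from unit-scale images")
        h, w = img.pixels.shape
        if h < patch_size or w < patch_size:
            skipped += 1
            continue
        top = int(rng.integers(0, h - patch_size + 1))
        left = int(rng.integers(0, w - patch_size + 1))
        patches.append(img.pixels[top : top + patch_size, left : left + patch_size])
        origins.append((top, left))
    if skipped:
        warnings.warn(
            f"skipped {skipped} image(s) smaller than the {patch_size}px patch",
            stacklevel=2,
        )
    if not patches:
        raise ValueError(f"no image is at least {patch_size}x{patch_size}; nothing to train on")
    stack = np.stack(patches)
    if return_origins:
        return stack, origins
    return stack


def lr_schedule(epoch: int, base_lr: float = 1e-4, halving_period: int = 2000) -> float:
    """Step decay: ``base_lr * 0.5 ** floor(epoch / halving_period)``."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    if halving_period < 1:
        raise ValueError("halving_period must be >= 1")
    return float(base_lr) * 0.5 ** (int(epoch) // int(halving_period))


def _batched(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(
    images: list[GrayImage],
    config: TrainConfig,
    *,
    repeat_index: int = 0,
    step_callback=None,
) -> TrainResult:
    """Run one adversarial training run and return the trained networks.

    ``step_callback(step, components)``, when given, is invoked after every
    optimizer step with the raw loss components (used by audits and tests).
    """
    if not images:
        raise ValueError("train requires a nonempty image list")
    root = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x7247, int(repeat_index)])
    net_seed, critic_seed, extractor_seed, data_seed = (
        int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in root.spawn(4)
    )
    net = DenoisingUNet(config.generator, seed=net_seed)
    critic = PatchCritic(config.discriminator, seed=critic_seed)
    extractor = create_extractor(
        config.perceptual_backend, seed=extractor_seed, channels=config.perceptual_channels
    )
    opt_g = Adam(net.parameters(), lr=config.base_lr)
    opt_d = Adam(critic.parameters(), lr=config.base_lr)
    data_rng = np.random.default_rng(data_seed)
    noise_params = SpeckleParams(
        sigma_8bit=config.sigma_8bit, r=config.noise_exponent, seed=0, clip=True
    )
    dtype = config.generator.np_dtype

    net.train()
    critic.train()
    history: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config.base_lr, config.lr_halving_period)
        opt_g.lr = lr
        opt_d.lr = lr
        clean_all = extract_patches(images, config.patch_size, data_rng)
        sums = {"l1": 0.0, "perceptual": 0.0, "adversarial": 0.0, "joint": 0.0, "critic": 0.0}
        n_steps = 0
        for idx in _batched(len(clean_all), config.batch_size, data_rng):
            clean_np = clean_all[idx]
            if config.augmentation:
                ks = data_rng.integers(0, 8, size=len(idx))
                clean_np = np.stack([dihedral_transform(p, int(k)) for p, k in zip(clean_np, ks)])
            noisy_np = np.stack(
                [
                    add_speckle(GrayImage(p, Scale.UNIT), noise_params, rng=data_rng).pixels
                    for p in clean_np
                ]
            )
            clean = Tensor(clean_np.astype(dtype)[..., None])
            noisy = Tensor(noisy_np.astype(dtype)[..., None])

            # one generator forward serves both updates
            fake = net(noisy)

            # critic update on detached denoised output
            opt_d.zero_grad()
            _, real_logit = critic(clean)
            _, fake_logit_det = critic(Tensor(fake.data))
            d_loss = discriminator_loss(real_logit, fake_logit_det)
            d_loss.backward()
            opt_d.step()

            # generator update against the refreshed critic
            opt_g.zero_grad()
            opt_d.zero_grad()  # clears stray critic grads from the joint graph
            _, fake_logit = critic(fake)
            l1 = l1_loss(fake, clean)
            lper = perceptual_loss(clean, fake, extractor)
            ladv = generator_adversarial_loss(fake_logit)
            g_loss = joint_loss(l1, lper, ladv, config.loss_weights)
            g_loss.backward()
            opt_g.step()
            opt_d.zero_grad()

            components = {
                "l1": l1.item(),
                "perceptual": lper.item(),
                "adversarial": ladv.item(),
                "joint": g_loss.item(),
                "critic": d_loss.item(),
            }
            if not all(math.isfinite(v) for v in components.values()):
                raise RuntimeError(f"non-finite loss at epoch {epoch} step {step}: {components}")
            for key, v in components.items():
                sums[key] += v
            n_steps += 1
            step += 1
            if step_callback is not None:
                step_callback(step, components)
            trim_heap()  # milliseconds per call; caps heap fragmentation growth
        history.append(
            {"epoch": epoch, "lr": lr, "steps": n_steps}
            | {k: sums[k] / n_steps for k in sums}
        )
    return TrainResult(net, critic, history, config, repeat_index)


def train_repeats(images: list[GrayImage], config: TrainConfig) -> list[TrainResult]:
    """The study's triple-repeat protocol: independent runs from derived seeds."""
    return [train(images, config, repeat_index=i) for i in range(config.repeats)]
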