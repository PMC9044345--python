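"""Patch sampling, augmentation, the LR schedule, and the adversarial loop."""

import hashlib

import numpy as np
import pytest
from scipy import stats

from despeckle.discriminator import DiscriminatorConfig, PatchCritic
from despeckle.generator import DenoisingUNet, GeneratorConfig
from despeckle.image import GrayImage, Scale
from despeckle.losses import (
    RandomConvFeatures,
    discriminator_loss,
    generator_adversarial_loss,
    joint_loss,
    l1_loss,
    perceptual_loss,
)
from despeckle.nn import Adam
from despeckle.nn.autograd import Tensor
from despeckle.phantom import PhantomSpec, generate_dataset
from despeckle.training import (
    TrainConfig,
    dihedral_inverse,
    dihedral_transform,
    extract_patches,
    lr_schedule,
    train,
)

# ---------------------------------------------------------------- lr schedule


def test_lr_schedule_halves_every_period():
    assert lr_schedule(0) == 1e-4
    assert lr_schedule(1999) == 1e-4
    assert lr_schedule(2000) == 5e-5
    assert lr_schedule(4000) == 2.5e-5
    assert lr_schedule(6000) == 1.25e-5


def test_lr_schedule_respects_custom_base_and_period():
    assert lr_schedule(10, base_lr=1e-3, halving_period=5) == pytest.approx(2.5e-4)


def test_lr_schedule_rejects_negative_epoch():
    with pytest.raises(ValueError):
        lr_schedule(-1)


# ------------------------------------------------------------------- dihedral


def test_dihedral_transforms_are_distinct_and_invertible():
    patch = np.arange(16.0).reshape(4, 4)
    results = [dihedral_transform(patch, k) for k in range(8)]
    for k, res in enumerate(results):
        np.testing.assert_array_equal(
            dihedral_transform(res, dihedral_inverse(k)), patch
        )
        np.testing.assert_array_equal(np.sort(res, axis=None), np.sort(patch, axis=None))
    flattened = {res.tobytes() for res in results}
    assert len(flattened) == 8


def test_dihedral_pairs_transform_identically():
    rng = np.random.default_rng(3)
    clean = rng.random((6, 6))
    noise = rng.standard_normal((6, 6))
    for k in range(8):
        a = dihedral_transform(clean + noise, k)
        b = dihedral_transform(clean, k) + dihedral_transform(noise, k)
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_dihedral_rejects_odd_rotation_of_non_square():
    with pytest.raises(ValueError, match="non-square"):
        dihedral_transform(np.zeros((2, 3)), 1)
    # even rotations and mirrors of non-square patches are fine
    assert dihedral_transform(np.zeros((2, 3)), 2).shape == (2, 3)


def test_dihedral_rejects_bad_index():
    with pytest.raises(ValueError):
        dihedral_transform(np.zeros((2, 2)), 8)
    with pytest.raises(ValueError):
        dihedral_inverse(-1)


# ------------------------------------------------------------- patch sampling


def test_extract_patches_shapes_and_bounds():
    rng = np.random.default_rng(0)
    images = [GrayImage(np.random.default_rng(i).random((40, 50)), Scale.UNIT) for i in range(5)]
    patches = extract_patches(images, 32, rng)
    assert patches.shape == (5, 32, 32)


def test_extract_patch_origins_are_uniform():
    # 12x12 image, 8px patch -> 25 possible origins; chi-square uniformity
    img = GrayImage(np.random.default_rng(1).random((12, 12)), Scale.UNIT)
    rng = np.random.default_rng(2)
    counts = np.zeros(25)
    n = 5000
    for _ in range(n):
        _, origins = extract_patches([img], 8, rng, return_origins=True)
        top, left = origins[0]
        counts[top * 5 + left] += 1
    chi2 = np.sum((counts - n / 25) ** 2 / (n / 25))
    assert chi2 < stats.chi2.ppf(0.999, df=24)


def test_extract_patches_skips_small_images_with_warning():
    big = GrayImage(np.ones((40, 40)), Scale.UNIT)
    small = GrayImage(np.ones((10, 10)), Scale.UNIT)
    with pytest.warns(UserWarning, match="skipped 1"):
        patches = extract_patches([big, small], 32, np.random.default_rng(0))
    assert patches.shape == (1, 32, 32)


def test_extract_patches_all_too_small_is_an_error():
    small = GrayImage(np.ones((10, 10)), Scale.UNIT)
    with pytest.raises(ValueError, match="nothing to train"):
        extract_patches([small], 32, np.random.default_rng(0))


# -------------------------------------------------------------- training loop


def _param_digest(module):
    h = hashlib.sha256()
    for name, p in module.named_parameters():
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def test_parameter_isolation_between_updates():
    """The critic step must not move the generator and vice versa."""
    rng = np.random.default_rng(9)
    net = DenoisingUNet(GeneratorConfig.scaled(16), seed=1)
    critic = PatchCritic(DiscriminatorConfig.scaled(16), seed=2)
    extractor = RandomConvFeatures(channels=8, seed=3)
    opt_g, opt_d = Adam(net.parameters(), lr=1e-3), Adam(critic.parameters(), lr=1e-3)
    clean = Tensor(rng.random((2, 32, 32, 1), dtype=np.float32))
    noisy = Tensor(rng.random((2, 32, 32, 1), dtype=np.float32))
    net.train()
    critic.train()
    fake = net(noisy)

    g_before = _param_digest(net)
    opt_d.zero_grad()
    _, real_logit = critic(clean)
    _, fake_logit = critic(Tensor(fake.data))
    discriminator_loss(real_logit, fake_logit).backward()
    opt_d.step()
    assert _param_digest(net) == g_before  # critic update left the generator alone

    d_before = _param_digest(critic)
    opt_g.zero_grad()
    opt_d.zero_grad()
    _, fake_logit = critic(fake)
    loss = joint_loss(
        l1_loss(fake, clean),
        perceptual_loss(clean, fake, extractor),
        generator_adversarial_loss(fake_logit),
    )
    loss.backward()
    opt_g.step()
    assert _param_digest(critic) == d_before  # generator update left the critic alone
    assert _param_digest(net) != g_before  # and did move the generator


def test_zero_epochs_returns_initialized_networks_and_empty_history():
    images = generate_dataset(2, PhantomSpec(seed=1))
    config = TrainConfig.smoke(epochs=0, seed=4)
    result = train(images, config)
    assert result.history == []
    fresh_like = DenoisingUNet(config.generator, seed=0)
    assert result.generator.n_parameters() == fresh_like.n_parameters()


def test_one_epoch_logs_components_and_lr():
    images = generate_dataset(4, PhantomSpec(seed=2))
    config = TrainConfig.smoke(epochs=1, seed=5)
    steps = []
    result = train(images, config, step_callback=lambda s, c: steps.append(c))
    assert len(result.history) == 1
    record = result.history[0]
    assert record["lr"] == config.base_lr
    for key in ("l1", "perceptual", "adversarial", "joint", "critic"):
        assert np.isfinite(record[key]) and record[key] >= 0
    # logged joint equals the lambda-combination of its logged components
    for comp in steps:
        expected = comp["l1"] + 0.1 * comp["perceptual"] + comp["adversarial"]
        assert comp["joint"] == pytest.approx(expected, rel=1e-6)


def test_empty_image_list_rejected():
    with pytest.raises(ValueError):
        train([], TrainConfig.smoke(epochs=1))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        TrainConfig(epochs=-1)
    with pytest.raises(ValueError):
        TrainConfig(base_lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(repeats=0)
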