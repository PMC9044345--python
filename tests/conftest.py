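import numpy as np
import pytest

from despeckle.discriminator import DiscriminatorConfig, PatchCritic
from despeckle.generator import DenoisingUNet, GeneratorConfig
from despeckle.image import GrayImage, Scale
from despeckle.phantom import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_gen_config():
    # 1/16-width plan (8, 16, 32, 64): same topology, desk-scale cost
    return GeneratorConfig.scaled(16)


@pytest.fixture(scope="session")
def tiny_disc_config():
    return DiscriminatorConfig.scaled(16)


@pytest.fixture(scope="session")
def tiny_generator(tiny_gen_config):
    return DenoisingUNet(tiny_gen_config, seed=7)


@pytest.fixture(scope="session")
def tiny_critic(tiny_disc_config):
    return PatchCritic(tiny_disc_config, seed=7)


@pytest.fixture(scope="session")
def phantoms64():
    return generate_dataset(8, PhantomSpec(height=64, width=64, seed=11))


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.random((32, 32)), Scale.UNIT)
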