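import numpy as np
import pytest

from polyerv import synthforge


@pytest.fixture(scope="session")
def small_config() -> synthforge.SimConfig:
    """A 1 Mb single-run world small enough for end-to-end tests."""
    return synthforge.SimConfig(
        backbone_length=1_000_000,
        n_chromosomes=1,
        n_shared_insertions=10,
        n_private_A=8,
        n_private_B=5,
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def small_world(small_config) -> synthforge.World:
    return synthforge.forge_world(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
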