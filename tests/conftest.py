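import numpy as np
import pytest

from utemri import (
    CONES_UTE,
    PhantomConfig,
    SpioDepot,
    generate_phantom,
    simulate_series,
)


@pytest.fixture(scope="session")
def phantom_spio():
    """Default-size phantom, SPIO-injected joint-space rate (64 s^-1), no depot."""
    return generate_phantom(PhantomConfig(spio_group=True), seed=0)


@pytest.fixture(scope="session")
def phantom_control():
    """Default-size phantom, control joint-space rate (70 s^-1), no depot."""
    return generate_phantom(PhantomConfig(spio_group=False), seed=0)


@pytest.fixture(scope="session")
def phantom_small():
    """64x64 phantom for noise / replicate tests."""
    return generate_phantom(PhantomConfig(shape=(64, 64), spio_group=True), seed=0)


@pytest.fixture(scope="session")
def phantom_depot():
    """Phantom with a focal SPIO depot in the fat pad (blooming source)."""
    return generate_phantom(
        PhantomConfig(spio_group=True, spio_depot=SpioDepot()), seed=0
    )


@pytest.fixture(scope="session")
def cones_noiseless(phantom_spio):
    return simulate_series(phantom_spio, CONES_UTE, noise_sigma=0.0)
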