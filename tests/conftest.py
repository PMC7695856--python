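import numpy as np
import pytest

from placentadce import (
    AcquisitionProtocol,
    ParameterGrid,
    PhantomConfig,
    Relaxivity,
    generate_phantom,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def relaxivity():
    return Relaxivity()


@pytest.fixture(scope="session")
def coarse_grid():
    return ParameterGrid.coarse()


@pytest.fixture(scope="session")
def small_phantom_cfg(coarse_grid):
    """Small on-grid phantom (fast) for end-to-end fitting tests."""
    return PhantomConfig(
        shape=(24, 24, 2), canal_radius=3.0, outer_radius=10.0,
        seed=7, snap_grid=coarse_grid,
    )


@pytest.fixture(scope="session")
def small_noise_free_phantom(small_phantom_cfg):
    import dataclasses

    cfg = dataclasses.replace(small_phantom_cfg, snr=np.inf)
    return generate_phantom(cfg), cfg
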