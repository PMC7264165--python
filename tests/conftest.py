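import numpy as np
import pytest

from envconn import (
    SimulationConfig,
    build_toy_leadfield,
    grid_source_space,
)


@pytest.fixture(scope="session")
def small_space():
    """27-source 3x3x3 grid at 5 mm."""
    return grid_source_space((3, 3, 3), 5.0, (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def small_forward(small_space):
    return build_toy_leadfield(small_space, 24, np.random.default_rng(7))


@pytest.fixture(scope="session")
def medium_space():
    """100-source 5x5x4 grid at 5 mm (used for inversion tests)."""
    return grid_source_space((5, 5, 4), 5.0, (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def medium_forward(medium_space):
    return build_toy_leadfield(medium_space, 30, np.random.default_rng(11))


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-top conditions for fast end-to-end runs."""
    return SimulationConfig(
        n_subjects=4,
        duration_s=20.0,
        fs_hz=100.0,
        n_sensors=24,
        grid_shape=(3, 3, 3),
        spacing_mm=5.0,
        bands=("theta", "alpha"),
        rng_seed=13,
    )
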