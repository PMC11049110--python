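import numpy as np
import pytest

from holotox.optics import OpticalConfig
from holotox.scenes import generate_phase_scene


@pytest.fixture(scope="session")
def optics_small() -> OpticalConfig:
    """Desk-scale geometry: 128x128 grid, same physical FOV and carrier."""
    return OpticalConfig(pixel_count_x=128, pixel_count_y=128)


@pytest.fixture(scope="session")
def optics_default() -> OpticalConfig:
    """Full 512x512 geometry used by the imaging system."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def scene_small(optics_small):
    return generate_phase_scene(optics_small, n_cells=8, mean_cell_mass_pg=300.0, seed=7)


@pytest.fixture(scope="session")
def scene_default(optics_default):
    return generate_phase_scene(optics_default, n_cells=30, mean_cell_mass_pg=300.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
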