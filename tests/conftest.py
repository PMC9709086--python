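import numpy as np
import pytest

from acoustoholo.config import RunConfig
from acoustoholo.samples import PRESETS, bead_scene


@pytest.fixture(scope="session")
def paa_bead_scene():
    """5 µm soft (PAA) bead in water on a small grid."""
    return bead_scene(
        5.0, PRESETS["PAA"], PRESETS["DI_water"], grid_shape=(64, 64), pixel_pitch=0.2
    )


@pytest.fixture(scope="session")
def small_bead_config():
    """Fast noise-free bead acquisition config used across tests."""
    return RunConfig(
        scene={"kind": "bead", "diameter": 5.0, "material": "PAA", "medium": "DI_water"},
        grid_shape=(64, 64),
        pixel_pitch=0.2,
        pressure=500.0,
        seed=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
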