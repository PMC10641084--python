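import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from bpfscope.config import EvalConfig, OpticalConfig
from bpfscope.optics import make_pupil_grid


@pytest.fixture(scope="session")
def paper_optics() -> OpticalConfig:
    """The experimental configuration: 0.75 NA, 525 nm, 33.3x, 6.5 um pixels."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def fine_optics() -> OpticalConfig:
    """Finely sampled grid for profile-fitting work (pitch 0.0875 um)."""
    return OpticalConfig(grid_size=256, pupil_diameter_px=64)


@pytest.fixture(scope="session")
def small_optics() -> OpticalConfig:
    """Tiny grid for gradient checks and fast tests."""
    return OpticalConfig(grid_size=16, pupil_diameter_px=8)


@pytest.fixture(scope="session")
def eval_cfg() -> EvalConfig:
    return EvalConfig()


@pytest.fixture(scope="session")
def fine_grid(fine_optics):
    return make_pupil_grid(fine_optics)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
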