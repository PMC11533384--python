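import numpy as np
import pytest

from opmbench.array_geometry import build_helmet_array
from opmbench.forward_models import SourceGrid, compute_leadfield


@pytest.fixture(scope="session")
def helmet():
    """Default 64-sensor (192-channel) helmet."""
    return build_helmet_array(seed=0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Small 1-cm grid for fast beamformer unit tests."""
    return SourceGrid.sphere_interior(radius=0.07, spacing=0.01)


@pytest.fixture(scope="session")
def coarse_leadfield(helmet, coarse_grid):
    return compute_leadfield(coarse_grid, helmet)


@pytest.fixture(scope="session")
def fine_grid():
    """4-mm grid used by localisation checks."""
    return SourceGrid.sphere_interior(radius=0.075, spacing=0.004)


@pytest.fixture(scope="session")
def fine_leadfield(helmet, fine_grid):
    return compute_leadfield(fine_grid, helmet)


def rng(seed=0):
    return np.random.default_rng(seed)
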