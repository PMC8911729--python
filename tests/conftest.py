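import numpy as np
import pytest

from saxsdic import (
    DetectorGeometry,
    FibrilGroundTruth,
    Profile1D,
    synthetic_geometry,
)
from saxsdic.geometry import RADIAL_Q


@pytest.fixture(scope="session")
def beamline_geometry():
    """Full-size photon-counting detector geometry (5.5 m, 172 um, 14 keV)."""
    return DetectorGeometry(
        distance=5.5,
        pixel_size=172.0,
        beam_center=(737.0, 839.0),
        energy=14.0,
        frame_shape=(1475, 1679),
    )


@pytest.fixture(scope="session")
def desk_geometry():
    """Desk-scale 256x256 geometry used for simulated frames."""
    return synthetic_geometry((256, 256))


@pytest.fixture(scope="session")
def small_geometry():
    """Tiny 128x128 geometry for fast integration tests."""
    return synthetic_geometry((128, 128))


@pytest.fixture(scope="session")
def default_truth():
    return FibrilGroundTruth()


def make_radial_profile(model, q_lo=0.40, q_hi=0.52, n_bins=120, counts=200):
    """Profile1D on a uniform q grid from a callable intensity model."""
    grid = np.linspace(q_lo + (q_hi - q_lo) / (2 * n_bins),
                       q_hi - (q_hi - q_lo) / (2 * n_bins), n_bins)
    return Profile1D(RADIAL_Q, grid, model(grid),
                     np.full(n_bins, counts, dtype=int))


@pytest.fixture
def radial_profile_factory():
    return make_radial_profile
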