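import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from henlepol.config import SceneGeometry
from henlepol.polarization import StokesMap

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    """Full-scale en-face geometry (28°×21°, 1024×250 px)."""
    return SceneGeometry()


@pytest.fixture(scope="session")
def small_geom():
    """Quarter-resolution geometry for cheaper simulations."""
    return SceneGeometry(grid_px=(512, 128))


@pytest.fixture(scope="session")
def square_geom():
    """Nearly isotropic toy grid for hand-checkable pattern tests."""
    return SceneGeometry(field_deg=(16.0, 16.0), grid_px=(160, 160))


def stokes_from_direction(qn, un, vn, intensity=1.0):
    """StokesMap with the given unit direction at every pixel."""
    qn, un, vn = np.broadcast_arrays(*(np.atleast_2d(np.asarray(a, float))
                                       for a in (qn, un, vn)))
    i = np.full(qn.shape, intensity)
    return StokesMap(i, intensity * qn, intensity * un, intensity * vn)
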