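import numpy as np
import pytest

from stickflow.io import RunConfig
from stickflow.phantom import default_gradient_table, make_crossing_phantom


def angle_deg(u, v) -> float:
    """Axial (sign-free) angle between two directions, in degrees."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


@pytest.fixture(scope="session")
def gtab():
    """The reference encoding: 1 b=0 + 55 b=1000 dispersed directions."""
    return default_gradient_table()


@pytest.fixture(scope="session")
def gtab_small():
    """A reduced encoding (1 b=0 + 12 directions) for fast I/O-level tests."""
    return default_gradient_table(12)


@pytest.fixture(scope="session")
def crossing90(gtab):
    """Noise-free 90-degree crossing phantom."""
    return make_crossing_phantom(90.0, (0.4, 0.4), grid_shape=(16, 16, 9),
                                 table=gtab, snr=np.inf)


@pytest.fixture()
def config():
    return RunConfig()
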