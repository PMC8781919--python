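import numpy as np
import pytest

from cbreco import make_geometry


@pytest.fixture
def small_geometry():
    """65x65 detector, odd-sized so one pixel sits exactly on the central ray."""
    angles = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    return make_geometry(scd=100.0, sdd=200.0, pixel_size=0.4, n_u=65, n_v=65,
                         angles=angles)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
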