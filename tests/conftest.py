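import numpy as np
import pytest

from corralsim import ParticleSpec, SystemGeometry


@pytest.fixture(scope="session")
def pip2():
    return ParticleSpec()


@pytest.fixture
def small_geometry():
    """A compact box for fast dynamics tests (corral boundary at 0)."""
    return SystemGeometry(
        box_x_lo=-60.0, box_x_hi=140.0, box_y_lo=-50.0, box_y_hi=50.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
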