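import numpy as np
import pytest

from optoloop.microscope import LexyGeometry, Optics
from optoloop.plants import LexyPlant, MigratingCell


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def optics():
    return Optics(shape=(64, 64), pixel_size=1.0, psf_sigma=1.0,
                  background=100.0, read_noise=2.0)


@pytest.fixture
def migrating_cell():
    return MigratingCell(position=np.array([32.0, 32.0]),
                         polarity=(1.0, 0.0))


@pytest.fixture
def lexy_plant():
    return LexyPlant()


@pytest.fixture
def lexy_geometry():
    return LexyGeometry(center=np.array([32.0, 32.0]))
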