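import numpy as np
import pytest

from twocolor_sfx.core import DetectorGeometry, UnitCell
from twocolor_sfx.synth import reduced_geometry, tetragonal_lysozyme_cell


@pytest.fixture(scope="session")
def lyso_cell() -> UnitCell:
    """Tetragonal lysozyme cell of the emulated study."""
    return tetragonal_lysozyme_cell()


@pytest.fixture(scope="session")
def geom2() -> DetectorGeometry:
    """Desk-scale two-panel detector (2048 x 512) at 51.03 mm."""
    return reduced_geometry(2)


@pytest.fixture(scope="session")
def small_geom() -> DetectorGeometry:
    """Tiny single-panel detector for constructed-image tests."""
    return DetectorGeometry(n_panels=1, panel_shape=(64, 64),
                            beam_center=(32.0, 32.0))


@pytest.fixture(scope="session")
def mid_geom() -> DetectorGeometry:
    """Square single-panel detector subtending wide angles, for oracles."""
    return DetectorGeometry(n_panels=1, panel_shape=(1024, 1024),
                            beam_center=(512.0, 512.0))


@pytest.fixture(scope="session")
def small_cell() -> UnitCell:
    """Small tetragonal cell keeping brute-force reflection boxes tiny."""
    return UnitCell(20.0, 20.0, 15.0, lattice_system="tetragonal")


def gaussian_blob(shape, center, sigma, amplitude):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((ys - center[0]) ** 2 + (xs - center[1]) ** 2)
                              / (2.0 * sigma ** 2))
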