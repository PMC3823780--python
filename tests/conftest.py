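import numpy as np
import pytest

from spiralfilm import (
    DoseGrid,
    PlanarDoseMap,
    SpiralGeometry,
)
from spiralfilm.synthetic import default_calibration_curve


@pytest.fixture(scope="session")
def geom():
    """The default published phantom geometry."""
    return SpiralGeometry()


@pytest.fixture(scope="session")
def curve():
    """The synthetic generating calibration curve (b, c, n) = (300, 500, 2.5)."""
    return default_calibration_curve()


@pytest.fixture
def affine_grid():
    """Grid sampled from D = 2x + 3y - z + 20 (strictly positive on domain)."""
    xs = np.arange(-3.0, 3.01, 0.5)
    zs = np.arange(-2.0, 2.01, 0.5)
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    vals = 2 * X + 3 * Y - Z + 20
    grid = DoseGrid(vals, origin=[xs[0], xs[0], zs[0]], spacing=[0.5, 0.5, 0.5])
    grid.affine = lambda p: 2 * p[..., 0] + 3 * p[..., 1] - p[..., 2] + 20
    return grid


def gradient_pair(pitch=0.1, nv=21, nu=81, shift_mm=3.0, slope=1.0, base=100.0):
    """Measured map with a linear u-gradient (slope cGy/mm, base at center)
    and the same map shifted by shift_mm in u, both built analytically."""
    u_mm = (np.arange(nu) + 0.5) * pitch * 10
    uc = u_mm.mean()
    dm = base + slope * (u_mm - uc)
    dc = base + slope * (u_mm - shift_mm - uc)
    measured = PlanarDoseMap(np.tile(dm, (nv, 1)), pitch=(pitch, pitch))
    calculated = PlanarDoseMap(np.tile(dc, (nv, 1)), pitch=(pitch, pitch))
    return measured, calculated


@pytest.fixture
def shifted_gradient():
    return gradient_pair()
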