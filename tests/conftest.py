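import numpy as np
import pytest

from glioquant.geometry_io import CellMark, NucleusROI


@pytest.fixture
def square_roi():
    """400 x 250 px rectangular nucleus boundary."""
    return NucleusROI("s1", "MNTB", ((0, 0), (400, 0), (400, 250), (0, 250)))


@pytest.fixture
def unit_square_roi():
    return NucleusROI("s1", "MNTB", ((0, 0), (1, 0), (1, 1), (0, 1)))


def random_simple_polygon(rng: np.random.Generator, n_vertices: int = 12,
                          radius: float = 100.0, center=(150.0, 150.0)):
    """Star-shaped (hence simple) polygon with random radii."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    return tuple(
        (center[0] + r * np.cos(a), center[1] + r * np.sin(a))
        for a, r in zip(angles, radii)
    )


def mark(x, y, markers=("Olig2",), section="s1", nucleus="MNTB", dia=None):
    return CellMark(section, nucleus, x, y, frozenset(markers), dia)
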