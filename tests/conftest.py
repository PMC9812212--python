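import numpy as np
import pytest

from xtalsim import DetectorGeometry, SpaceGroup, UnitCell
from xtalsim.fixtures import make_point_lattice, make_toy_asu_crystal
from xtalsim.scattering import load_table


@pytest.fixture(scope="session")
def table():
    return load_table()


@pytest.fixture(scope="session")
def small_geom():
    """A coarse 40x32 detector used by fast engine tests."""
    return DetectorGeometry(
        wavelength=1.54, distance=40.0, pixel_size=0.5,
        n_fast=40, n_slow=32, beam_center=(20.0, 16.0),
    )


@pytest.fixture(scope="session")
def p43212():
    return SpaceGroup.from_symbol("P43212")


@pytest.fixture(scope="session")
def toy_cell():
    return UnitCell(20.0, 20.0, 14.0)


@pytest.fixture(scope="session")
def toy_crystal(p43212, toy_cell):
    """640-atom P43212 toy crystal (20-atom asu, 8 ops, 2x2x1 cells)."""
    return make_toy_asu_crystal(p43212, toy_cell, (2, 2, 1), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_amplitude(xyz, elements, occ, q_pts, s, table, b=None):
    """Independent per-atom complex-sum oracle (plain loops, no engine code)."""
    import cmath

    out = []
    for qi, si in zip(q_pts, s):
        total = 0j
        for j in range(len(xyz)):
            f = table[elements[j]].evaluate(si)
            if b is not None:
                f *= np.exp(-b[j] * si * si)
            phase = 2.0 * np.pi * float(np.dot(xyz[j], qi))
            total += occ[j] * f * cmath.exp(1j * phase)
        out.append(total)
    return np.array(out)
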