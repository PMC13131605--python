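import numpy as np
import pytest

from epivertex import mechanics as mech
from epivertex import tissue_geometry as tg


@pytest.fixture(scope="session")
def tiny_tissue():
    """9 basal cells, one suprabasal layer; shared read-only across tests."""
    return tg.build_initial_tissue(9, 1, jitter=0.2, seed=11)


@pytest.fixture(scope="session")
def small_tissue():
    """Roughly 20 interacting cells for force-oracle tests (random geometry)."""
    return tg.build_initial_tissue(16, 1, jitter=0.25, seed=7)


@pytest.fixture()
def e14_params():
    return mech.stage_to_params("E14")


@pytest.fixture()
def e16_params():
    return mech.stage_to_params("E16")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def finite_difference_forces(tess, params, vertex_ids, h=1e-6):
    """Central finite differences of the energy, the independent force oracle."""
    out = np.zeros((len(vertex_ids), 3))
    for row, v in enumerate(vertex_ids):
        for d in range(3):
            tess.verts[v, d] += h
            tess.invalidate()
            ep = mech.energy(tess, params)
            tess.verts[v, d] -= 2 * h
            tess.invalidate()
            em = mech.energy(tess, params)
            tess.verts[v, d] += h
            tess.invalidate()
            out[row, d] = -(ep - em) / (2 * h)
    return out
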