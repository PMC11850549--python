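import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import epivertex as ev

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def unit_square():
    return ev.make_polygon_cell([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def honeycomb():
    return ev.make_hexagonal_fixture(4, 4)


@pytest.fixture(scope="session")
def params():
    return ev.ModelParams()


@pytest.fixture(scope="session")
def small_tissue():
    """~50-cell Lloyd-relaxed clamped tiling with types assigned."""
    cfg = ev.InitConfig(n_cells=50, box_size=11.18, patch_size=4.5, seed=5)
    return ev.build_tissue(cfg), cfg


def fd_force(mesh, params, v, h=1e-6):
    """Central finite-difference force on vertex v (test oracle)."""
    out = np.zeros(2)
    for k in range(2):
        old = mesh.vx[v, k]
        mesh.vx[v, k] = old + h
        ep = ev.tissue_energy(mesh, params)
        mesh.vx[v, k] = old - h
        em = ev.tissue_energy(mesh, params)
        mesh.vx[v, k] = old
        out[k] = -(ep - em) / (2 * h)
    return out
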