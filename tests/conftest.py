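import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epivertex.mesh import build_hexagonal_lattice, hexagon_side_for_area

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: side length giving unit hexagon area
UNIT_SIDE = hexagon_side_for_area(1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_lattice7():
    """7-cell lattice of unit-area hexagons."""
    return build_hexagonal_lattice(7, UNIT_SIDE)


def jittered_lattice(n_cells: int, seed: int, jitter: float = 0.08):
    """Small lattice with jittered vertices (still simple polygons)."""
    mesh = build_hexagonal_lattice(n_cells, UNIT_SIDE)
    r = np.random.default_rng(seed)
    mesh.vertices = mesh.vertices + r.normal(0.0, jitter * UNIT_SIDE, mesh.vertices.shape)
    return mesh
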