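"""Shared fixtures: small domains, meshes and steady states that several
test modules reuse (session-scoped to keep the suite fast)."""

import numpy as np
import pytest

from budmorph import geometry as G
from budmorph.fem_solver import solve_steady
from budmorph.rd_models import ModelSpec
from budmorph.synthetic_data import ShapeSpec, fixture_parameters, make_bud_shape


@pytest.fixture(scope="session")
def circle_points():
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    return 50.0 * np.column_stack([np.cos(th), np.sin(th)])


@pytest.fixture(scope="session")
def small_disc_domain():
    """Disc epithelium (radius 15) in a circular mesenchyme (radius 45)."""
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    epi = G.BoundaryCurve(15.0 * np.column_stack([np.cos(th), np.sin(th)]))
    ell = G.Ellipse2D(np.zeros(2), (45.0001, 45.0), np.array([1.0, 0.0]))
    return G.TwoLayerDomain((epi,), ell)


@pytest.fixture(scope="session")
def small_disc_mesh(small_disc_domain):
    return G.build_mesh(small_disc_domain, target_h=1.5)


@pytest.fixture(scope="session")
def t1_fine_model():
    return ModelSpec("T1", fixture_parameters()["T1_fine"])


@pytest.fixture(scope="session")
def t1_fine_state(t1_fine_model, small_disc_mesh):
    state = solve_steady(t1_fine_model, small_disc_mesh, tol=1e-7, seed=0)
    assert state.converged
    return state


@pytest.fixture(scope="session")
def two_bud_small():
    """Small two-bud epithelium for pipeline tests."""
    return make_bud_shape(ShapeSpec(base=(30.0, 18.0),
                                    buds=((0.55, 12.0, 0.38),
                                          (2.55, 12.0, 0.38))))
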