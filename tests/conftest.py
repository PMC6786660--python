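"""Shared fixtures: default parameter set and cached meshes/solves."""

import pytest
from hypothesis import settings

import c4cell as c

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return c.ModelParams()


@pytest.fixture(scope="session")
def geometry(params):
    return c.build_geometry(params)


@pytest.fixture(scope="session")
def mesh_default(geometry):
    """Production-resolution mesh (8 cells/um)."""
    return c.build_mesh(geometry, 8.0)


@pytest.fixture(scope="session")
def mesh_coarse(geometry):
    """Coarse mesh for oracle comparisons and fast unit tests."""
    return c.build_mesh(geometry, 4.0)


@pytest.fixture(scope="session")
def c3_state(params, mesh_default):
    """Converged default (pure C3) steady state on the production mesh."""
    return c.solve_steady_state(params, c.SolverOptions(), mesh=mesh_default)


@pytest.fixture(scope="session")
def c3_state_coarse(params, mesh_coarse):
    return c.solve_steady_state(params, c.SolverOptions(), mesh=mesh_coarse)


@pytest.fixture(scope="session")
def c4_state(params, mesh_default):
    """Saturating-pump steady state (capacity ratio 10)."""
    c_p = c.pepc_for_capacity_ratio(params, mesh_default.geometry, 10.0)
    return c.solve_steady_state(params.replace(c_P=c_p), c.SolverOptions(), mesh=mesh_default)
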