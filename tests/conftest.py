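import numpy as np
import pytest

from biosensim.flow_solver import FlowSolver, FluidProperties, uniform_inlet
from biosensim.mesh import GeometryConfig, build_channel_mesh


@pytest.fixture()
def unit_square():
    """Single unit-square element corner coordinates."""
    x4 = np.array([0.0, 1.0, 1.0, 0.0])
    y4 = np.array([0.0, 0.0, 1.0, 1.0])
    return x4, y4


@pytest.fixture()
def mesh3x3():
    g = GeometryConfig(L=1.0, H=1.0, Ls=1.0, Nx=3, Ny=3, Ns=3)
    return build_channel_mesh(g)


@pytest.fixture(scope="session")
def poiseuille_run():
    """Steady flow in a straight channel on the acceptance mesh (81x41)."""
    H, L, u0 = 1e-3, 3e-3, 7e-6
    g = GeometryConfig(L=L, H=H, Ls=L, Nx=81, Ny=41, Ns=81)
    mesh = build_channel_mesh(g)
    solver = FlowSolver(mesh, FluidProperties(rho=1000.0, mu=1e-3), uniform_inlet(mesh, u0))
    state = solver.steady(tol=1e-8)
    return {"mesh": mesh, "solver": solver, "state": state, "u0": u0, "H": H, "L": L}


@pytest.fixture(scope="session")
def validation_run():
    """The packaged validation case, run to its full 1e5 s window."""
    from biosensim.driver_io import run_binding_cycle
    from biosensim.oracles import validation_fixture

    config = validation_fixture()
    return {"config": config, "result": run_binding_cycle(config)}
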