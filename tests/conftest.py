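import numpy as np
import pytest

from thromboflow.grid import StructuredGrid
from thromboflow.flow import FlowSolver, NumericsConfig


def make_channel(ny=40, nx=120, h=1e-3):
    """Open planar channel grid: inlet west, outlet east, walls north/south."""
    dy = h / ny
    return StructuredGrid(nx=nx, ny=ny, dx=dy, dy=dy,
                          fluid_mask=np.ones((ny, nx), dtype=bool))


def make_closed_box(n=8, d=1e-3):
    """Closed square cavity: fluid cells surrounded by walls, no inlet."""
    fm = np.zeros((n + 2, n + 2), dtype=bool)
    fm[1:-1, 1:-1] = True
    return StructuredGrid(nx=n + 2, ny=n + 2, dx=d / n, dy=d / n,
                          fluid_mask=fm)


@pytest.fixture(scope="session")
def poiseuille():
    """Developed laminar channel flow: U=0.01 m/s mean, 40 cells across."""
    g = make_channel(ny=40, nx=120)
    mu, rho, U = 3.5e-3, 1060.0, 0.01
    fs = FlowSolver(g, rho=rho, numerics=NumericsConfig(dt=2e-3))
    st = fs.initial_state(mu0=mu)
    for _ in range(500):
        st = fs.step(st, u_inlet=U, p_out=0.0)
    return {"grid": g, "state": st, "solver": fs, "mu": mu, "rho": rho,
            "U": U, "h": g.ny * g.dy}
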