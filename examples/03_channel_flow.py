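"""Validating the flow solver on plane Poiseuille flow.

Drives a 1 mm channel with a flat inlet profile and lets the profile
develop; the centreline velocity of laminar channel flow is exactly 1.5x
the mean, and the wall shear stress is 6 mu U / h.
"""

import numpy as np

from thromboflow import FlowSolver, NumericsConfig
from thromboflow.grid import StructuredGrid
from thromboflow.metrics import wall_shear_stress

ny, nx = 40, 120
h = 1e-3
g = StructuredGrid(nx=nx, ny=ny, dx=h / ny, dy=h / ny,
                   fluid_mask=np.ones((ny, nx), dtype=bool))
mu, rho, U = 3.5e-3, 1060.0, 0.01
fs = FlowSolver(g, rho=rho, numerics=NumericsConfig(dt=2e-3))
st = fs.initial_state(mu0=mu)
for _ in range(500):
    st = fs.step(st, u_inlet=U, p_out=0.0)

prof = st.u[:, int(0.9 * nx)]
tau, _ = wall_shear_stress(st, g)
mid = np.isclose(g.wall_faces.x, (int(0.9 * nx) + 0.5) * g.dx)
print(f"centreline / mean velocity : {prof.max()/prof.mean():.4f} (exact 1.5)")
print(f"wall shear stress          : {tau[mid].mean()*1e3:.3f} mPa "
      f"(analytic {6*mu*U/h*1e3:.3f} mPa)")
print(f"max cell divergence        : {st.div_max:.2e} 1/s")
q_in, q_out = fs.boundary_fluxes(st)
print(f"mass balance inlet/outlet  : {q_in:.6e} / {q_out:.6e} m^3/s")
print("-> the projection step keeps the face velocity field divergence-free")
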