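"""Incompressible non-Newtonian Navier-Stokes on the structured grid.

The momentum equation carries the thrombus momentum sink,

    rho du/dt + rho u.grad(u) = -grad(p) + div(mu (grad u + grad u^T)) - S_M,
    S_M = k_M BP^2/(BP^2 + BP_t^2) u,

and is advanced with a semi-implicit fractional-step (projection) scheme on
a colocated cell-centred grid:

* predictor: implicit first-order upwind advection + implicit variable-
  viscosity diffusion + implicit momentum sink (the sink coefficient reaches
  k_M = 1e7 kg/m^3/s inside a clot, so explicit treatment is hopeless);
* projection: a pressure Poisson solve on compact face-interpolated
  velocities, after which the *face* velocities are discretely
  divergence-free to linear-solver accuracy.

Boundary conditions: plug Dirichlet velocity at the inlet, no-slip walls,
zero-gradient velocity with Dirichlet pressure (Windkessel or zero) at the
outlet, symmetry on the axis in axisymmetric mode.  The viscous term uses
the Laplacian form div(mu grad u); in axisymmetric mode the radial component
carries the additional -mu v/r^2 curvature term and all fluxes are
area-weighted by radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import StructuredGrid, W, E, S, N, INTERIOR, WALL, INLET, OUTLET, AXIS

__all__ = ["FlowState", "NumericsConfig", "FlowSolver", "momentum_sink",
           "sink_coefficient"]

_SIGN = {W: -1.0, E: 1.0, S: -1.0, N: 1.0}


@dataclass
class NumericsConfig:
    """Time-stepping and solver controls.

    ``dt`` is the reporting/physics step (the momentum scheme is implicit in
    advection, diffusion and sink, so it remains stable at advective CFL > 1;
    species transport sub-cycles internally to ``scalar_cfl``).
    """

    dt: float = 0.005
    cycles_flow_init: int = 2
    cycles_total: int = 20
    scalar_cfl: float = 0.9
    pressure_tol: float = 1e-10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class FlowState:
    """Velocity/pressure/viscosity at one time level (full 2-D arrays).

    ``uf``/``vf`` are the face normal velocities ((ny, nx+1) and (ny+1, nx));
    after a projection step they are discretely divergence-free and are the
    velocities that advect scalars.  ``div_max`` records the worst cell
    divergence (1/s) of the last projection.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mu: np.ndarray
    uf: np.ndarray
    vf: np.ndarray
    t: float = 0.0
    rho: float = 1060.0
    div_max: float = 0.0


def sink_coefficient(bp, k_m: float, bp_t: float):
    """Brinkman-type sink coefficient k_M BP^2/(BP^2+BP_t^2) [kg/m^3/s]."""
    bp = np.asarray(bp, dtype=float)
    return k_m * bp * bp / (bp * bp + bp_t * bp_t)


def momentum_sink(bp, u, v, k_m: float = 1e7, bp_t: float = 20.0):
    """Momentum sink force density (S_x, S_y), parallel to the velocity."""
    s = sink_coefficient(bp, k_m, bp_t)
    return s * np.asarray(u, dtype=float), s * np.asarray(v, dtype=float)


class FlowSolver:
    """Projection-method advancer bound to one grid.

    The pressure Poisson operator depends only on geometry and density, so it
    is factorised once; the momentum operator is rebuilt every step because
    advection, viscosity and the clot sink all evolve.
    """

    def __init__(self, grid: StructuredGrid, rho: float = 1060.0,
                 numerics: NumericsConfig = None):
        self.g = grid
        self.rho = float(rho)
        self.num = numerics or NumericsConfig()
        g = grid
        n = g.n_fluid
        self.n = n
        nx, ny = g.nx, g.ny

        # gather indices into flattened face arrays, per direction
        jj, ii = g.jj, g.ii
        self._fidx = {
            W: jj * (nx + 1) + ii,
            E: jj * (nx + 1) + ii + 1,
            S: jj * nx + ii,
            N: (jj + 1) * nx + ii,
        }

        fm = g.fluid_mask
        self._xf_int = fm[:, :-1] & fm[:, 1:]           # (ny, nx-1)
        self._yf_int = fm[:-1, :] & fm[1:, :]           # (ny-1, nx)
        self._inlet_col = fm[:, 0]
        self._outlet_col = fm[:, -1]

        self._build_pressure_operator()

    # ------------------------------------------------------------------
    def _build_pressure_operator(self):
        g, rho, n = self.g, self.rho, self.n
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        idx = np.arange(n)
        self._out_coef = np.zeros(n)    # outlet Dirichlet coefficient (per cell)
        for d in range(4):
            c = g.face_area[d] / (rho * g.face_dist[d])
            m = g.face_kind[d] == INTERIOR
            rows.append(idx[m]); cols.append(g.nb[d][m]); vals.append(-c[m])
            diag[m] += c[m]
            mo = g.face_kind[d] == OUTLET
            diag[mo] += c[mo]
            self._out_coef[mo] = c[mo]
        self._closed = not bool((g.face_kind == OUTLET).any())
        if self._closed:
            diag[0] += 1.0              # pin the gauge in closed domains
        rows.append(idx); cols.append(idx); vals.append(diag)
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        self._p_lu = spla.splu(A.tocsc())

    # ------------------------------------------------------------------
    def initial_state(self, mu0: float = 3.5e-3) -> FlowState:
        g = self.g
        z = np.zeros((g.ny, g.nx))
        return FlowState(u=z.copy(), v=z.copy(), p=z.copy(),
                         mu=np.full((g.ny, g.nx), mu0),
                         uf=np.zeros((g.ny, g.nx + 1)),
                         vf=np.zeros((g.ny + 1, g.nx)),
                         t=0.0, rho=self.rho)

    # ------------------------------------------------------------------
    def _outflux(self, uf, vf):
        """Volumetric outward flux [m^3/s] through each face, per direction."""
        g = self.g
        ufl, vfl = uf.ravel(), vf.ravel()
        out = {}
        for d in range(4):
            vals = (ufl if d in (W, E) else vfl)[self._fidx[d]]
            out[d] = _SIGN[d] * vals * g.face_area[d]
        return out

    def divergence(self, uf, vf):
        """Per-cell net outflux divided by cell volume [1/s]."""
        q = self._outflux(uf, vf)
        return (q[W] + q[E] + q[S] + q[N]) / self.g.volume

    def boundary_fluxes(self, state: FlowState):
        """(Q_in, Q_out) volumetric fluxes through inlet and outlet [m^3/s]."""
        g = self.g
        a_in = g.face_area[W][g.inlet_cells]
        a_out = g.face_area[E][g.outlet_cells]
        q_in = float((state.uf[:, 0][g.jj[g.inlet_cells]] * a_in).sum())
        q_out = float((state.uf[:, -1][g.jj[g.outlet_cells]] * a_out).sum())
        return q_in, q_out

    # ------------------------------------------------------------------
    def step(self, st: FlowState, sink=None, u_inlet: float = 0.0,
             p_out: float = 0.0, dt: float = None) -> FlowState:
        """Advance one time step; returns a new :class:`FlowState`.

        ``sink`` is the clot sink coefficient field (full array or per-fluid
        vector, kg/m^3/s); ``u_inlet`` the plug inlet velocity; ``p_out`` the
        outlet pressure (ignored for closed domains).
        """
        g, rho, n = self.g, self.rho, self.n
        dt = self.num.dt if dt is None else dt
        mu = g.pack(st.mu)
        if sink is None:
            s = np.zeros(n)
        else:
            s = np.asarray(sink, dtype=float)
            if s.ndim == 2:
                s = g.pack(s)

        uo = g.pack(st.u)
        vo = g.pack(st.v)
        vol = g.volume
        idx = np.arange(n)

        q = self._outflux(st.uf, st.vf)
        # old-pressure gradient (incremental projection: the Poisson step
        # then solves only for a correction, which vanishes at steady state)
        pfx_o, pfy_o = self._pressure_faces(st.p, p_out)
        px_o = g.pack(np.diff(pfx_o, axis=1)) / g.dx
        py_o = g.pack(np.diff(pfy_o, axis=0)) / g.dy
        diag = rho * vol / dt + s * vol
        rhs_u = rho * vol / dt * uo - vol * px_o
        rhs_v = rho * vol / dt * vo - vol * py_o
        rows, cols, vals = [], [], []
        for d in range(4):
            kindd = g.face_kind[d]
            F = rho * q[d]
            mu_nb = np.where(g.nb[d] >= 0, mu[g.nb[d]], mu)
            mu_f = 2.0 * mu * mu_nb / (mu + mu_nb)
            Dc = mu_f * g.face_area[d] / g.face_dist[d]
            anb = Dc + np.maximum(-F, 0.0)

            m = kindd == INTERIOR
            rows.append(idx[m]); cols.append(g.nb[d][m]); vals.append(-anb[m])
            diag += np.where(m, anb + F, 0.0)

            mw = kindd == WALL
            diag += np.where(mw, anb, 0.0)          # Dirichlet 0, F=0 at walls

            mi = kindd == INLET
            diag += np.where(mi, anb + F, 0.0)
            rhs_u += np.where(mi, anb * u_inlet, 0.0)

            mo = kindd == OUTLET
            diag += np.where(mo, F, 0.0)            # zero-gradient outflow
            # AXIS faces carry zero area in axisymmetric mode: nothing to do

        rows.append(idx); cols.append(idx)
        rows = np.concatenate(rows); cols = np.concatenate(cols)
        offvals = np.concatenate(vals + [diag])
        A_u = sp.csr_matrix((offvals, (rows, cols)), shape=(n, n))
        if g.axisymmetric:
            extra = mu * vol / g.r_center ** 2
            A_v = A_u + sp.diags(extra)
            lu_u = spla.splu(A_u.tocsc())
            ustar = lu_u.solve(rhs_u)
            vstar = spla.splu(A_v.tocsc()).solve(rhs_v)
        else:
            lu = spla.splu(A_u.tocsc())
            ustar = lu.solve(rhs_u)
            vstar = lu.solve(rhs_v)

        # --- face velocities of the predictor ---------------------------
        u2 = g.full(ustar)
        v2 = g.full(vstar)
        uf = np.zeros_like(st.uf)
        vf = np.zeros_like(st.vf)
        uf[:, 1:-1] = np.where(self._xf_int, 0.5 * (u2[:, :-1] + u2[:, 1:]), 0.0)
        uf[:, 0] = np.where(self._inlet_col, u_inlet, 0.0)
        uf[:, -1] = np.where(self._outlet_col, u2[:, -1], 0.0)
        vf[1:-1, :] = np.where(self._yf_int, 0.5 * (v2[:-1, :] + v2[1:, :]), 0.0)

        # --- pressure-correction Poisson --------------------------------
        div = self.divergence(uf, vf) * vol         # net outflux per cell
        rhs_p = -div / dt                           # correction: 0 at outlet
        dpvec = self._p_lu.solve(rhs_p)
        dp2 = g.full(dpvec)
        p2 = st.p + dp2
        p2[~g.fluid_mask] = 0.0

        # --- correct faces with the pressure correction -----------------
        c = dt / rho
        uf[:, 1:-1] -= np.where(self._xf_int,
                                c * (dp2[:, 1:] - dp2[:, :-1]) / g.dx, 0.0)
        uf[:, -1] -= np.where(self._outlet_col,
                              c * (0.0 - dp2[:, -1]) / (g.dx / 2.0), 0.0)
        vf[1:-1, :] -= np.where(self._yf_int,
                                c * (dp2[1:, :] - dp2[:-1, :]) / g.dy, 0.0)

        # --- correct cell-centred velocities ----------------------------
        fm = g.fluid_mask
        dpfx, dpfy = self._pressure_faces(dp2, 0.0)
        un = u2 - c * np.diff(dpfx, axis=1) / g.dx
        vn = v2 - c * np.diff(dpfy, axis=0) / g.dy
        un[~fm] = 0.0
        vn[~fm] = 0.0

        div_max = float(np.abs(self.divergence(uf, vf)).max()) if n else 0.0
        return FlowState(u=un, v=vn, p=p2, mu=st.mu, uf=uf, vf=vf,
                         t=st.t + dt, rho=rho, div_max=div_max)

    # ------------------------------------------------------------------
    def _pressure_faces(self, p2: np.ndarray, p_out: float):
        """Face values of a cell pressure field.

        Interior faces average the two cells; walls, inlet and axis are
        Neumann (one-sided cell value); the outlet face carries the Dirichlet
        value ``p_out``.
        """
        g = self.g
        fm = g.fluid_mask
        pfx = np.zeros((g.ny, g.nx + 1))
        left, right = fm[:, :-1], fm[:, 1:]
        pfx[:, 1:-1] = np.where(self._xf_int, 0.5 * (p2[:, :-1] + p2[:, 1:]),
                                np.where(left, p2[:, :-1],
                                         np.where(right, p2[:, 1:], 0.0)))
        pfx[:, 0] = np.where(fm[:, 0], p2[:, 0], 0.0)
        pfx[:, -1] = np.where(fm[:, -1],
                              p2[:, -1] if self._closed else p_out, 0.0)
        pfy = np.zeros((g.ny + 1, g.nx))
        lo, hi = fm[:-1, :], fm[1:, :]
        pfy[1:-1, :] = np.where(self._yf_int, 0.5 * (p2[:-1, :] + p2[1:, :]),
                                np.where(lo, p2[:-1, :],
                                         np.where(hi, p2[1:, :], 0.0)))
        pfy[0, :] = np.where(fm[0, :], p2[0, :], 0.0)
        pfy[-1, :] = np.where(fm[-1, :], p2[-1, :], 0.0)
        return pfx, pfy
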