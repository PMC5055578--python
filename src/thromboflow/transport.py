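"""Coupled scalar transport for the thrombosis model.

Five fields live on the fluid cells:

* ``RT`` — residence time [s]: advected tracer with a unit source,
  dRT/dt + v.grad(RT) = D_RT lap(RT) + 1, RT = 0 at the inlet.  Its increase
  over one averaging window, divided by the window, is the relative
  residence time RRT (1 = fully stagnant).
* ``RP``/``AP`` — resting/activated platelets, normalised by their inlet
  values (2.5e8 and 1.25e7 platelets/mL): convection-diffusion-reaction
  with the shear-enhanced diffusivity D_p = D_pt + alpha*gdot and the
  activation pair r1 = k1 [AP][RP], r2 = k2_eff [RP] RRT.  The reaction
  conserves total platelet number (RP_ref RP + AP_ref AP).
* ``C`` — lumped coagulant [nmol/L]: produced at low-shear walls (Dirichlet
  100 nmol/L where the window-averaged wall shear rate is below the wall
  threshold, 0 elsewhere, zero-flux on arch walls) and in the bulk at rate
  k_c phi_C(BP) phi_g; it spreads *diffusively only*, with the shear-gated
  effective diffusivity phi_g * D_c — the moving-boundary surrogate for
  diffusion-limited surface reactions on a growing clot.
* ``BP`` — bound platelets [nmol/L]: immobile, monotonically accumulating
  at rate k_BP phi_BP(C, RRT) phi_g [AP].

All gating uses the smooth switching function x^2/(x^2+x_t^2) so the model
turns growth on and off without discontinuities, and phi_g =
g_t^2/(gbar^2+g_t^2) suppresses both coagulant spreading and platelet
binding wherever the window-averaged shear rate is high.

Advection/diffusion of RT/RP/AP is explicit first-order upwind with
automatic sub-cycling to a CFL limit (positivity-preserving); the coagulant
diffusion is implicit — unconditionally stable whatever the calibrated D_c
— with its operator refactorised only when the shear gates update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import StructuredGrid, W, E, S, N, INTERIOR, INLET

__all__ = ["KineticParams", "SpeciesState", "TransportSolver", "saturation",
           "phi_shear", "platelet_diffusivity", "activation_sources",
           "coagulant_wall_values"]

_SIGN = {W: -1.0, E: 1.0, S: -1.0, N: 1.0}


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants, diffusivities and thresholds (SI units).

    Dimensional notes: ``k2`` is the raw thrombin-pathway constant in
    mL/platelets/s; with concentrations normalised the effective first-order
    rate is ``k2_eff = k2 * ap_ref = 0.15 1/s``.  ``d_pt`` and ``alpha`` are
    the platelet thermal diffusivity and the shear-enhancement coefficient
    (1.6e-9 cm^2/s and 7e-9 cm^2 in CGS).  ``d_c`` is the coagulant base
    diffusivity, which is a calibrated model parameter (see docs/methods.md).
    Shear thresholds: ``gamma_bulk_t``/``gamma_wall_t`` default to the
    pulsatile-phantom values (100 and 90 1/s); the steady BFS benchmark uses
    10 and 1 1/s.
    """

    k1: float = 0.5                  # 1/s
    k2: float = 1.2e-8               # mL/platelets/s
    k2_eff: float = 0.15             # 1/s
    k_c: float = 200.0               # nmol/L/s
    k_bp: float = 10.0               # nmol/L/s
    k_m: float = 1e7                 # kg/m^3/s
    d_rt: float = 1.14e-11           # m^2/s
    d_pt: float = 1.6e-13            # m^2/s
    alpha: float = 7e-13             # m^2
    d_c: float = 1e-8                # m^2/s (calibrated, see docs/methods.md)
    rrt_t: float = 0.9
    c_t: float = 10.0                # nmol/L
    bp_t: float = 20.0               # nmol/L
    gamma_bulk_t: float = 100.0      # 1/s
    gamma_wall_t: float = 90.0       # 1/s
    gamma_activation_t: float = 1e4  # 1/s, diagnostic threshold
    c_wall: float = 100.0            # nmol/L
    background_activation: float = 0.05
    rp_inlet: float = 2.5e8          # platelets/mL
    ap_ref: float = 1.25e7           # platelets/mL
    adhesion_rate: float = 5e-5      # m/s

    @property
    def ap_scale(self) -> float:
        """Physical RP-to-AP conversion factor rp_inlet/ap_ref (=20)."""
        return self.rp_inlet / self.ap_ref


@dataclass
class SpeciesState:
    """The five scalar fields (full 2-D arrays, zero in solid cells)."""

    rt: np.ndarray
    rp: np.ndarray
    ap: np.ndarray
    c: np.ndarray
    bp: np.ndarray
    t: float = 0.0


# ---------------------------------------------------------------------------
def saturation(x, x_t):
    """Switching function x^2/(x^2+x_t^2) in [0, 1)."""
    if x_t <= 0:
        raise ValueError("saturation threshold must be positive")
    x = np.asarray(x, dtype=float)
    return x * x / (x * x + x_t * x_t)


def phi_shear(gamma_bar, gamma_t):
    """Shear gate g_t^2/(gbar^2+g_t^2): 1 at rest, -> 0 at high shear."""
    g = np.asarray(gamma_bar, dtype=float)
    return gamma_t * gamma_t / (g * g + gamma_t * gamma_t)


def platelet_diffusivity(gamma_dot, params: KineticParams = KineticParams()):
    """Shear-enhanced platelet diffusivity D_pt + alpha*gdot [m^2/s]."""
    return params.d_pt + params.alpha * np.asarray(gamma_dot, dtype=float)


def activation_sources(ap, rp, rrt, params: KineticParams = KineticParams()):
    """Reaction sources (S_AP, S_RP) in normalised units per second.

    r1 = k1 [AP][RP] is activation by activated platelets, r2 = k2_eff [RP]
    RRT the residence-time-scaled thrombin surrogate.  S_RP = -(r1+r2);
    S_AP carries the factor rp_inlet/ap_ref so that physical platelet number
    is conserved by the pair.
    """
    ap = np.asarray(ap, dtype=float)
    rp = np.asarray(rp, dtype=float)
    rrt = np.asarray(rrt, dtype=float)
    if (ap < 0).any() or (rp < 0).any() or (rrt < 0).any():
        raise ValueError("normalised concentrations must be non-negative")
    r = params.k1 * ap * rp + params.k2_eff * rp * rrt
    return params.ap_scale * r, -r


def coagulant_wall_values(wall_gamma_bar, wall_faces,
                          params: KineticParams) -> np.ndarray:
    """Per-wall-face coagulant boundary condition.

    Returns an array aligned with ``wall_faces``: the Dirichlet value
    (``c_wall`` where the window-averaged wall shear rate is below
    ``gamma_wall_t``, else 0) or NaN on arch faces, which keep a zero-flux
    condition.
    """
    g = np.asarray(wall_gamma_bar, dtype=float)
    vals = np.where(g < params.gamma_wall_t, params.c_wall, 0.0)
    return np.where(wall_faces.is_arch, np.nan, vals)


# ---------------------------------------------------------------------------
class TransportSolver:
    """Advances RT, RP, AP, C and BP on one grid.

    Call :meth:`set_flow` with the divergence-free face velocities after each
    flow step, :meth:`update_gating` whenever the window averages roll, then
    the ``advance_*`` methods in the operator-split order RT -> platelets ->
    coagulant -> bound platelets.  All methods work on per-fluid-cell
    vectors.
    """

    def __init__(self, grid: StructuredGrid, params: KineticParams = None,
                 scalar_cfl: float = 0.9):
        self.g = grid
        self.p = params or KineticParams()
        self.cfl = scalar_cfl
        g = grid
        nx = g.nx
        jj, ii = g.jj, g.ii
        self._fidx = {
            W: jj * (nx + 1) + ii,
            E: jj * (nx + 1) + ii + 1,
            S: jj * nx + ii,
            N: (jj + 1) * nx + ii,
        }
        self._q = None
        self._qp = None
        self._qm = None
        # wall-face scatter info
        wf = g.wall_faces
        self._wf_cell = wf.cell
        self._wf_geom = wf.area / wf.dist          # A/d for Dirichlet coupling
        self._wf_area = wf.area
        self._c_lu = None
        self._c_rhs0 = None
        self._c_dt = None
        self._phi_g = None
        self._adh_mask = np.zeros(len(wf), dtype=bool)

    # -- flow coupling ---------------------------------------------------
    def set_flow(self, uf: np.ndarray, vf: np.ndarray) -> None:
        g = self.g
        ufl, vfl = uf.ravel(), vf.ravel()
        q = {}
        for d in range(4):
            vals = (ufl if d in (W, E) else vfl)[self._fidx[d]]
            q[d] = _SIGN[d] * vals * g.face_area[d]
        self._q = q
        self._qp = {d: np.maximum(q[d], 0.0) for d in range(4)}
        self._qm = {d: np.minimum(q[d], 0.0) for d in range(4)}

    # -- generic explicit upwind + diffusion sweep -----------------------
    def _advect_diffuse(self, c, d_field, inlet_vals, dt,
                        adhesion_rows=()):
        """Sub-cycled upwind advection + explicit diffusion.

        ``c``: (m, N) stacked species; ``d_field``: (m, N) diffusivities;
        ``inlet_vals``: (m,) Dirichlet inlet values; ``adhesion_rows``: rows
        that lose mass through first-order adhesion at low-shear wall faces
        flagged by :meth:`update_gating`.
        """
        if self._q is None:
            raise RuntimeError("set_flow must be called before transport")
        g, p = self.g, self.p
        c = np.atleast_2d(np.asarray(c, dtype=float)).copy()
        d_field = np.atleast_2d(d_field)
        m, n = c.shape
        vol = g.volume
        inlet_vals = np.asarray(inlet_vals, dtype=float).reshape(m, 1)

        nb_safe = {d: np.where(g.nb[d] >= 0, g.nb[d], 0) for d in range(4)}

        # stability rate: advective outflux + diffusive exchange per cell
        lam = np.zeros(n)
        dmax = d_field.max(axis=0)
        for d in range(4):
            lam += self._qp[d]
            geom = g.face_area[d] / g.face_dist[d]
            active = (g.face_kind[d] == INTERIOR) | (g.face_kind[d] == INLET)
            lam += np.where(active, dmax * geom, 0.0)
        adh = np.zeros(n)
        if len(adhesion_rows) and self._adh_mask.any():
            am = self._adh_mask
            np.add.at(adh, self._wf_cell[am],
                      p.adhesion_rate * self._wf_area[am])
            lam += adh
        lam /= vol
        nsub = max(1, int(np.ceil(dt * lam.max() / self.cfl))) if n else 1
        dts = dt / nsub

        for _ in range(nsub):
            flux = np.zeros_like(c)
            for d in range(4):
                kindd = g.face_kind[d]
                interior = kindd == INTERIOR
                inlet = kindd == INLET
                c_nb = np.where(interior, c[:, nb_safe[d]], c)
                c_nb = np.where(inlet, inlet_vals, c_nb)
                # upwind advective exchange (outlet/backflow use c_P)
                flux -= self._qp[d] * c
                flux -= self._qm[d] * np.where(interior | inlet, c_nb, c)
                # diffusion through interior and Dirichlet-inlet faces
                geom = g.face_area[d] / g.face_dist[d]
                df = np.where(interior,
                              0.5 * (d_field + d_field[:, nb_safe[d]]),
                              d_field)
                dif = df * geom * (c_nb - c)
                flux += np.where(interior | inlet, dif, 0.0)
            c = c + dts * flux / vol
            if len(adhesion_rows):
                for r in adhesion_rows:
                    c[r] -= dts * adh * c[r] / vol
        return c

    # -- residence time --------------------------------------------------
    def advance_residence_time(self, rt, dt):
        """One step of the residence-time tracer (unit source, RT=0 inlet)."""
        d = np.full((1, self.g.n_fluid), self.p.d_rt)
        out = self._advect_diffuse(rt[None, :], d, [0.0], dt)[0]
        out += dt
        out[self.g.inlet_cells] = 0.0
        return out

    # -- platelets -------------------------------------------------------
    def advance_platelets(self, rp, ap, gamma_dot, rrt, dt):
        """CDR advance of resting/activated platelets.

        Shear-enhanced diffusivity from the instantaneous shear rate;
        first-order adhesion loss on low-shear wall faces (set by
        :meth:`update_gating`); semi-implicit reaction pair that conserves
        physical platelet number exactly.
        """
        p = self.p
        dp = platelet_diffusivity(gamma_dot, p)
        d2 = np.vstack([dp, dp])
        stack = self._advect_diffuse(np.vstack([rp, ap]), d2, [1.0, 1.0], dt,
                                     adhesion_rows=(0, 1))
        rp, ap = stack[0], stack[1]
        rate = p.k1 * ap + p.k2_eff * np.maximum(rrt, 0.0)
        rp_new = rp / (1.0 + dt * rate)
        ap_new = ap + p.ap_scale * (rp - rp_new)
        return rp_new, ap_new

    # -- gating update (once per averaging window) -----------------------
    def update_gating(self, gamma_bar_cell, wall_gamma_bar, dt) -> None:
        """Rebuild shear gates, wall conditions and the coagulant operator.

        ``gamma_bar_cell``: window-averaged bulk shear rate per fluid cell;
        ``wall_gamma_bar``: window-averaged wall shear rate per wall face;
        ``dt`` the step size the implicit coagulant operator will be used
        with.
        """
        g, p = self.g, self.p
        self._phi_g = phi_shear(gamma_bar_cell, p.gamma_bulk_t)
        wall_vals = coagulant_wall_values(wall_gamma_bar, g.wall_faces, p)
        self._adh_mask = (~g.wall_faces.is_arch) & \
            (np.asarray(wall_gamma_bar) < p.gamma_wall_t)

        # implicit diffusion operator for the coagulant
        n = g.n_fluid
        d_eff = self._phi_g * p.d_c
        rows, cols, vals = [], [], []
        diag = g.volume / dt
        idx = np.arange(n)
        for d in range(4):
            interior = g.face_kind[d] == INTERIOR
            nb = g.nb[d]
            nbs = np.where(nb >= 0, nb, 0)
            df = np.where(interior, 0.5 * (d_eff + d_eff[nbs]), 0.0)
            coef = df * g.face_area[d] / g.face_dist[d]
            rows.append(idx[interior]); cols.append(nb[interior])
            vals.append(-coef[interior])
            diag = diag + np.where(interior, coef, 0.0)
        rhs0 = np.zeros(n)
        dirichlet = ~np.isnan(wall_vals)
        if dirichlet.any():
            cells = self._wf_cell[dirichlet]
            coef = d_eff[cells] * self._wf_geom[dirichlet]
            np.add.at(diag, cells, coef)
            np.add.at(rhs0, cells, coef * wall_vals[dirichlet])
        rows.append(idx); cols.append(idx); vals.append(diag)
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        self._c_lu = spla.splu(A.tocsc())
        self._c_rhs0 = rhs0
        self._c_dt = dt

    @property
    def phi_g(self):
        """Current bulk shear gate field (per fluid cell)."""
        return self._phi_g

    @property
    def adhesion_faces(self):
        """Boolean mask over wall faces where platelet adhesion is active."""
        return self._adh_mask

    # -- coagulant -------------------------------------------------------
    def advance_coagulant(self, c, bp, dt):
        """Implicit diffusion + volumetric source k_c phi_C(BP) phi_g."""
        if self._c_lu is None:
            raise RuntimeError("update_gating must be called before the coagulant")
        if abs(dt - self._c_dt) > 1e-12 * self._c_dt:
            raise ValueError("coagulant operator was built for a different dt")
        p = self.p
        src = p.k_c * saturation(bp, p.bp_t) * self._phi_g
        rhs = self.g.volume * (c / dt + src) + self._c_rhs0
        return self._c_lu.solve(rhs)

    # -- bound platelets -------------------------------------------------
    def advance_bound_platelets(self, bp, c, ap, rrt, dt):
        """BP += dt k_BP phi_BP(C, RRT) phi_g [AP]; immobile, monotone."""
        p = self.p
        phi_bp = saturation(c, p.c_t) * saturation(np.maximum(rrt, 0.0), p.rrt_t)
        return bp + dt * p.k_bp * phi_bp * self._phi_g * np.maximum(ap, 0.0)
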