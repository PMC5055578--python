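"""Species transport: residence time, platelets, coagulant, bound platelets."""

import numpy as np
import pytest
from dataclasses import replace

from thromboflow.transport import (KineticParams, TransportSolver,
                                   activation_sources, coagulant_wall_values,
                                   phi_shear, platelet_diffusivity, saturation)
from thromboflow.grid import PhantomSpec, build_phantom
from tests.conftest import make_channel, make_closed_box

KIN = KineticParams()


def still(solver):
    """Zero flow field for a grid-bound transport solver."""
    g = solver.g
    solver.set_flow(np.zeros((g.ny, g.nx + 1)), np.zeros((g.ny + 1, g.nx)))
    return solver


class TestPointwise:
    @pytest.mark.parametrize("x,xt,expect", [
        (0.0, 10.0, 0.0), (10.0, 10.0, 0.5), (30.0, 10.0, 0.9)])
    def test_saturation(self, x, xt, expect):
        assert saturation(x, xt) == pytest.approx(expect)

    @pytest.mark.parametrize("g,gt,expect", [
        (0.0, 100.0, 1.0), (100.0, 100.0, 0.5), (300.0, 100.0, 0.1)])
    def test_phi_shear(self, g, gt, expect):
        assert phi_shear(g, gt) == pytest.approx(expect)

    def test_platelet_diffusivity_affine(self):
        assert platelet_diffusivity(0.0, KIN) == pytest.approx(1.6e-13)
        # 100 1/s: 1.6e-9 + 7e-9*100 cm^2/s = 7.016e-7 cm^2/s = 7.016e-11 m^2/s
        assert platelet_diffusivity(100.0, KIN) == pytest.approx(7.016e-11)

    def test_activation_sources(self):
        s_ap, s_rp = activation_sources(0.0, 1.0, 0.0, KIN)
        assert s_ap == 0.0 and s_rp == 0.0
        s_ap, s_rp = activation_sources(1.0, 1.0, 0.0, KIN)
        assert s_rp == pytest.approx(-0.5)          # r1 = k1 AP RP
        assert s_ap == pytest.approx(0.5 * KIN.ap_scale)
        with pytest.raises(ValueError):
            activation_sources(-1.0, 1.0, 0.0, KIN)


class TestResidenceTime:
    def test_stagnant_closed_box_rt_equals_t(self):
        g = make_closed_box(n=6)
        ts = still(TransportSolver(g, KIN))
        rt = np.zeros(g.n_fluid)
        dt, nstep = 0.05, 40
        for _ in range(nstep):
            rt = ts.advance_residence_time(rt, dt)
        assert np.allclose(rt, dt * nstep, rtol=1e-3)

    def test_plug_flow_steady_profile(self):
        g = make_channel(ny=4, nx=50)
        ts = TransportSolver(g, KIN)
        v0 = 0.05
        uf = np.full((g.ny, g.nx + 1), v0)
        ts.set_flow(uf, np.zeros((g.ny + 1, g.nx)))
        rt = np.zeros(g.n_fluid)
        for _ in range(400):
            rt = ts.advance_residence_time(rt, 0.01)
        x = g.x_centers
        # steady state: RT ~ x/v (first-order upwind, half-cell offset)
        mid = (g.jj == 2)
        assert np.allclose(rt[mid], x[mid] / v0, atol=1.5 * g.dx / v0)

    def test_inlet_cells_stay_zero(self):
        g = make_channel(ny=4, nx=20)
        ts = still(TransportSolver(g, KIN))
        rt = np.zeros(g.n_fluid)
        for _ in range(10):
            rt = ts.advance_residence_time(rt, 0.01)
        assert np.all(rt[g.inlet_cells] == 0.0)


class TestPlatelets:
    def test_uniform_fields_unchanged_without_reactions(self):
        g = make_closed_box(n=5)
        kin = replace(KIN, k1=0.0, k2_eff=0.0)
        ts = still(TransportSolver(g, kin))
        rp, ap = np.ones(g.n_fluid), np.ones(g.n_fluid)
        rp2, ap2 = ts.advance_platelets(rp, ap, np.zeros(g.n_fluid),
                                        np.zeros(g.n_fluid), 0.01)
        assert np.allclose(rp2, 1.0, rtol=1e-14)
        assert np.allclose(ap2, 1.0, rtol=1e-14)

    def test_closed_box_platelet_number_conserved(self):
        """RP_ref*RP + AP_ref*AP invariant under the reaction pair."""
        g = make_closed_box(n=5)
        ts = still(TransportSolver(g, KIN))
        rp, ap = np.ones(g.n_fluid), np.ones(g.n_fluid)
        gam = np.zeros(g.n_fluid)
        rrt = np.ones(g.n_fluid)
        total0 = (rp + ap / KIN.ap_scale).sum()
        for _ in range(100):
            rp, ap = ts.advance_platelets(rp, ap, gam, rrt, 0.01)
        total = (rp + ap / KIN.ap_scale).sum()
        assert abs(total / total0 - 1) < 1e-10
        assert np.all(rp >= 0) and np.all(ap >= 0)

    def test_adhesion_depletes_platelets(self):
        g = make_closed_box(n=5)
        kin = replace(KIN, k1=0.0, k2_eff=0.0, gamma_wall_t=90.0)
        ts = still(TransportSolver(g, kin))
        nw = len(g.wall_faces)
        ts.update_gating(np.zeros(g.n_fluid), np.zeros(nw), 0.01)
        assert ts.adhesion_faces.all()
        rp, ap = np.ones(g.n_fluid), np.ones(g.n_fluid)
        for _ in range(20):
            rp, ap = ts.advance_platelets(rp, ap, np.zeros(g.n_fluid),
                                          np.zeros(g.n_fluid), 0.01)
        assert ap.sum() < g.n_fluid
        assert rp.sum() < g.n_fluid


class TestCoagulant:
    def test_wall_bc_selection(self):
        g = build_phantom(PhantomSpec.canonical("C1"), 1.0)
        wf = g.wall_faces
        wg = np.full(len(wf), 50.0)
        wg[~wf.is_arch][:1] = 200.0
        # construct: mix of low/high shear faces
        wg = np.where(np.arange(len(wf)) % 2 == 0, 50.0, 200.0)
        vals = coagulant_wall_values(wg, wf, KIN)
        non_arch = ~wf.is_arch
        low = non_arch & (wg < KIN.gamma_wall_t)
        high = non_arch & (wg >= KIN.gamma_wall_t)
        assert np.all(vals[low] == KIN.c_wall)
        assert np.all(vals[high] == 0.0)
        assert np.all(np.isnan(vals[wf.is_arch]))   # zero flux on the arch

    def test_no_source_no_wall_stays_zero(self):
        g = make_closed_box(n=5)
        ts = still(TransportSolver(g, KIN))
        nw = len(g.wall_faces)
        # high wall shear everywhere: Dirichlet 0 walls; BP=0: no source
        ts.update_gating(np.zeros(g.n_fluid), np.full(nw, 500.0), 0.01)
        c = np.zeros(g.n_fluid)
        for _ in range(10):
            c = ts.advance_coagulant(c, np.zeros(g.n_fluid), 0.01)
        assert np.allclose(c, 0.0)

    def test_stagnant_source_rate_is_kc(self):
        g = make_closed_box(n=5)
        kin = replace(KIN, d_c=1e-12)               # isolate the source term
        ts = still(TransportSolver(g, kin))
        nw = len(g.wall_faces)
        ts.update_gating(np.zeros(g.n_fluid), np.full(nw, 500.0), 0.01)
        c = ts.advance_coagulant(np.zeros(g.n_fluid),
                                 np.full(g.n_fluid, 1e4), 0.01)
        assert np.allclose(c, kin.k_c * 0.01, rtol=1e-3)

    def test_high_shear_suppression_100x(self):
        g = make_closed_box(n=5)
        kin = replace(KIN, d_c=1e-12)
        nw = len(g.wall_faces)
        bp = np.full(g.n_fluid, 1e4)
        out = {}
        for label, gam in [("still", 0.0), ("sheared", 1000.0)]:
            ts = still(TransportSolver(g, kin))
            ts.update_gating(np.full(g.n_fluid, gam), np.full(nw, 500.0), 0.01)
            out[label] = ts.advance_coagulant(np.zeros(g.n_fluid), bp, 0.01)
        ratio = out["still"].mean() / out["sheared"].mean()
        assert ratio == pytest.approx(101.0, rel=0.02)  # 1/phi(1000;100)


class TestBoundPlatelets:
    def _solver(self, phi_gamma=1.0):
        g = make_closed_box(n=4)
        ts = still(TransportSolver(g, KIN))
        nw = len(g.wall_faces)
        gam = np.zeros(g.n_fluid) if phi_gamma == 1.0 else None
        ts.update_gating(np.zeros(g.n_fluid), np.full(nw, 500.0), 0.01)
        return g, ts

    def test_zero_ap_means_no_growth(self):
        g, ts = self._solver()
        bp = np.full(g.n_fluid, 5.0)
        out = ts.advance_bound_platelets(bp, np.full(g.n_fluid, 100.0),
                                         np.zeros(g.n_fluid),
                                         np.ones(g.n_fluid), 0.01)
        assert np.array_equal(out, bp)

    def test_saturated_growth_rate_is_kbp(self):
        g, ts = self._solver()
        bp = ts.advance_bound_platelets(
            np.zeros(g.n_fluid), np.full(g.n_fluid, 1e4),
            np.ones(g.n_fluid), np.full(g.n_fluid, 1e4), 0.01)
        assert np.allclose(bp, KIN.k_bp * 0.01, rtol=1e-6)

    def test_low_coagulant_reduces_rate_tenfold(self):
        g, ts = self._solver()
        hi = ts.advance_bound_platelets(
            np.zeros(g.n_fluid), np.full(g.n_fluid, 1e4),
            np.ones(g.n_fluid), np.full(g.n_fluid, 1e4), 0.01)
        lo = ts.advance_bound_platelets(
            np.zeros(g.n_fluid), np.full(g.n_fluid, KIN.c_t / 3.0),
            np.ones(g.n_fluid), np.full(g.n_fluid, 1e4), 0.01)
        assert lo.mean() / hi.mean() == pytest.approx(0.1, rel=1e-3)

    def test_bp_monotone_nondecreasing(self):
        g, ts = self._solver()
        bp = np.zeros(g.n_fluid)
        rng = np.random.default_rng(0)
        for _ in range(20):
            prev = bp
            bp = ts.advance_bound_platelets(
                bp, rng.uniform(0, 30, g.n_fluid),
                rng.uniform(0, 2, g.n_fluid), rng.uniform(0, 1, g.n_fluid),
                0.01)
            assert np.all(bp >= prev)


def test_feedback_loop_propagates_from_seed():
    """A thrombosed seed in stagnant fluid produces coagulant that spreads
    and converts neighbouring cells (the growth feedback mechanism)."""
    g = make_closed_box(n=15, d=2e-3)
    kin = replace(KIN, d_c=1e-6)
    ts = still(TransportSolver(g, kin))
    nw = len(g.wall_faces)
    ts.update_gating(np.zeros(g.n_fluid), np.full(nw, 500.0), 0.01)
    bp = np.zeros(g.n_fluid)
    r2 = ((g.x_centers - g.x_centers.mean()) ** 2
          + (g.y_centers - g.y_centers.mean()) ** 2)
    bp[r2 < (2 * g.dx) ** 2] = 100.0            # thrombosed seed patch
    cc = np.zeros(g.n_fluid)
    ap = np.ones(g.n_fluid)
    rrt = np.ones(g.n_fluid)
    for _ in range(300):
        cc = ts.advance_coagulant(cc, bp, 0.01)
        bp = ts.advance_bound_platelets(bp, cc, ap, rrt, 0.01)
    assert cc.max() > KIN.c_t                      # coagulant was produced
    assert (bp >= KIN.bp_t).sum() > 1              # the front moved outward
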