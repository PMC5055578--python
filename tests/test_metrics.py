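"""Wall shear, flow split, thrombus extent, window averaging, growth knee."""

import numpy as np
import pytest

from thromboflow.grid import PhantomSpec, StepSpec, build_bfs, build_phantom
from thromboflow.metrics import (CycleAccumulator, growth_knee,
                                 relative_residence_time, thrombus_extent,
                                 update_cycle_averages, flow_split)
from tests.conftest import make_channel


class TestThrombusExtent:
    def test_empty_field(self):
        g = make_channel(ny=10, nx=20)
        m = thrombus_extent(np.zeros((g.ny, g.nx)), g, 20.0)
        assert m.area == 0.0 and m.height == 0.0 and m.length == 0.0

    def test_rectangular_patch(self):
        # 2 mm x 5 mm patch at 0.1 mm cells: height 2 mm, length 5 mm
        g = make_channel(ny=40, nx=100, h=4e-3)
        bp = np.zeros((g.ny, g.nx))
        bp[5:25, 10:60] = 50.0
        m = thrombus_extent(bp, g, 20.0)
        assert m.height == pytest.approx(2e-3)
        assert m.length == pytest.approx(5e-3)
        assert m.area == pytest.approx(1e-5)
        assert m.n_components == 1

    def test_two_disjoint_patches(self):
        g = make_channel(ny=20, nx=100, h=2e-3)
        bp = np.zeros((g.ny, g.nx))
        bp[2:6, 5:15] = 50.0           # 1 mm long
        bp[10:14, 40:70] = 50.0        # 3 mm long
        m = thrombus_extent(bp, g, 20.0)
        assert m.n_components == 2
        assert m.area == pytest.approx((4 * 10 + 4 * 30) * g.dx * g.dy)
        assert m.length == pytest.approx(3e-3)   # max per-component extent

    def test_bfs_height_measured_from_outer_wall(self):
        g = build_bfs(StepSpec(), resolution=2.0)
        bp = np.zeros((g.ny, g.nx))
        j0 = g.step_info["j_step"]
        i0 = g.step_info["i_step"]
        bp[j0:, i0:i0 + 20] = 50.0     # fills the step recess, 10 mm long
        m = thrombus_extent(bp, g, 20.0)
        assert m.height == pytest.approx(g.step_info["height"])
        assert m.length == pytest.approx(10e-3)


class TestFlowSplit:
    def test_manual_tear_flux_fraction(self):
        g = build_phantom(PhantomSpec.canonical("C1"), 1.0)

        class FakeState:
            uf = np.zeros((g.ny, g.nx + 1))
            vf = np.zeros((g.ny + 1, g.nx))
        st = FakeState()
        rows = g.jj[g.inlet_cells]
        st.uf[rows, 0] = 0.5                       # inlet plug
        o = g.tear_openings[0]
        st.vf[o["j_face"], o["i0"]:o["i1"]] = 0.2  # upward through the tear
        q_in = 0.5 * rows.size * g.dy
        q_tear = 0.2 * (o["i1"] - o["i0"]) * g.dx
        assert flow_split(st, g) == pytest.approx(100 * q_tear / q_in)

    def test_no_tears_returns_zero(self):
        g = make_channel()

        class FakeState:
            uf = np.ones((g.ny, g.nx + 1))
            vf = np.zeros((g.ny + 1, g.nx))
        assert flow_split(FakeState(), g) == 0.0


class TestCycleAveraging:
    def test_constant_field_average(self):
        g = make_channel(ny=4, nx=10)
        acc = CycleAccumulator(g, period=1.0)
        nw = len(g.wall_faces)
        for _ in range(10):
            acc.add_sample(0.1, np.full(g.n_fluid, 3.0), np.full(nw, 2.0),
                           np.full(nw, 0.5))
        avg = update_cycle_averages(acc)
        assert np.allclose(avg.mean_shear_rate, 3.0)
        assert np.allclose(avg.tawss, 0.5)

    def test_zero_mean_sinusoid_averages_out(self):
        g = make_channel(ny=4, nx=10)
        acc = CycleAccumulator(g, period=1.0)
        nw = len(g.wall_faces)
        n = 200
        for k in range(n):
            s = np.sin(2 * np.pi * (k + 0.5) / n)
            acc.add_sample(1.0 / n, np.full(g.n_fluid, s), np.zeros(nw),
                           np.zeros(nw))
        avg = acc.roll()
        assert np.abs(avg.mean_shear_rate).max() < 1e-12

    def test_incomplete_window_raises(self):
        g = make_channel(ny=4, nx=10)
        acc = CycleAccumulator(g, period=1.0)
        acc.add_sample(0.2, np.zeros(g.n_fluid),
                       np.zeros(len(g.wall_faces)), np.zeros(len(g.wall_faces)))
        with pytest.raises(ValueError):
            acc.roll()

    def test_rrt_definitions(self):
        # stagnant cell: RT grows by the full window -> RRT = 1;
        # flushed cell: no RT increase -> RRT = 0; fractional increase scales
        g = make_channel(ny=4, nx=10)
        acc = CycleAccumulator(g, period=2.0)
        rt0 = np.zeros(g.n_fluid)
        acc.start_window(0.0, rt0)
        acc.add_sample(2.0, np.zeros(g.n_fluid),
                       np.zeros(len(g.wall_faces)), np.zeros(len(g.wall_faces)))
        rt1 = np.zeros(g.n_fluid)
        rt1[0] = 2.0          # stagnant
        rt1[1] = 0.9 * 2.0    # partial
        avg = acc.roll(rt1)
        assert avg.rrt[0] == pytest.approx(1.0)
        assert avg.rrt[1] == pytest.approx(0.9)
        assert avg.rrt[2] == pytest.approx(0.0)
        assert relative_residence_time(0.45 * 2.0, 2.0) == pytest.approx(0.45)


def test_growth_knee_on_synthetic_curve():
    # 3 mm/s for 8 s, then 0.2 mm/s: knee at ~24 mm, rate ratio 15x
    t = np.arange(0, 50.0, 1.0)
    L = np.where(t <= 8, 3e-3 * t, 24e-3 + 0.2e-3 * (t - 8))
    knee, peak, late = growth_knee(t, L)
    assert peak == pytest.approx(3e-3, rel=0.2)
    assert late == pytest.approx(0.2e-3, rel=0.2)
    assert knee == pytest.approx(24e-3, rel=0.15)


def test_quasi_steady_tawss_equals_mean_flow_wss(poiseuille):
    """For steady (zero-Womersley limit) flow the window-averaged WSS equals
    the instantaneous WSS of the mean flow."""
    from thromboflow.metrics import wall_shear_stress
    g, st = poiseuille["grid"], poiseuille["state"]
    tau, gam = wall_shear_stress(st, g)
    acc = CycleAccumulator(g, period=0.5)
    for _ in range(5):
        acc.add_sample(0.1, np.zeros(g.n_fluid), gam, tau)
    avg = acc.roll()
    assert np.allclose(avg.tawss, tau)
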