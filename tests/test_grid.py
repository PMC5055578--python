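"""Geometry construction: phantoms, the step channel, wall classification."""

import numpy as np
import pytest

from thromboflow.grid import (GeometryError, PhantomSpec, StepSpec,
                              build_bfs, build_phantom, classify_wall_faces, W)
from tests.conftest import make_channel


def _tear_openings_widths(grid, spec, res):
    """Widths (mm) of contiguous fluid gaps in the flap strip."""
    n_tl = int(round(spec.true_lumen_width * res))
    row = grid.fluid_mask[n_tl, :]
    # contiguous runs of fluid in the flap row
    d = np.diff(np.concatenate([[0], row.astype(int), [0]]))
    starts, ends = np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]
    return sorted((ends - starts) / res)


@pytest.mark.parametrize("name,n_open,widths", [
    ("C1", 1, [10.0]),
    ("C2", 1, [10.0]),
    ("C3", 2, [5.0, 10.0]),
    ("C5", 2, [10.0, 10.0]),
    ("C6", 2, [10.0, 20.0]),
])
def test_phantom_tear_openings(name, n_open, widths):
    spec = PhantomSpec.canonical(name)
    res = 1.0
    g = build_phantom(spec, res)
    got = _tear_openings_widths(g, spec, res)
    assert len(got) == n_open
    assert got == pytest.approx(widths)


def test_phantom_fluid_area_analytic():
    spec = PhantomSpec.canonical("C5")
    res = 1.0
    g = build_phantom(spec, res)
    mm2 = 1e-6
    diss = spec.dissection_end - spec.dissection_start
    analytic = (spec.total_length * spec.true_lumen_width
                + diss * spec.false_lumen_width
                + sum(d for _, _, d in spec.tears()) * spec.flap_thickness) * mm2
    # within one cell layer of the fluid perimeter
    perim = 2 * (spec.total_length + spec.true_lumen_width
                 + diss + spec.false_lumen_width) * 1e-3
    assert abs(g.fluid_area() - analytic) < perim * g.dx


def test_phantom_refinement_area_stable():
    spec = PhantomSpec.canonical("C3")
    a1 = build_phantom(spec, 1.0).fluid_area()
    a2 = build_phantom(spec, 2.0).fluid_area()
    assert abs(a2 - a1) / a1 < 0.02


@pytest.mark.parametrize("bad", [
    dict(false_lumen_width=0.0),
    dict(flap_thickness=-1.0),
    dict(tear_axial_positions=(58.0,)),          # tear off the flap segment
])
def test_phantom_degenerate_specs_raise(bad):
    base = PhantomSpec.canonical("C1")
    spec = PhantomSpec(**{**base.__dict__, **bad})
    with pytest.raises(GeometryError):
        build_phantom(spec, 1.0)


def test_phantom_overlapping_tears_raise():
    spec = PhantomSpec(n_tears=2, proximal_tear_diameter=10.0,
                       distal_tear_diameter=10.0,
                       tear_axial_positions=(100.0, 105.0))
    with pytest.raises(GeometryError):
        build_phantom(spec, 1.0)


def test_phantom_under_resolved_tear_raises():
    # C3's 5 mm tear needs >= 4 cells: 0.5 cells/mm gives 2.5
    with pytest.raises(GeometryError):
        build_phantom(PhantomSpec.canonical("C3"), 0.5)


def test_bfs_default_dimensions():
    g = build_bfs(StepSpec(), resolution=4.0)
    si = g.step_info
    assert si["height"] == pytest.approx(2.5e-3)
    assert si["j_step"] == 20                  # 5 mm upstream radius at 4/mm
    # step resolved by 10 cells at 4 cells/mm
    assert g.ny - si["j_step"] == 10
    # downstream bore: upstream bore + 2 x step in diameter
    assert 2 * si["outer_radius"] == pytest.approx(15e-3)


def test_bfs_zero_step_is_straight_channel():
    g = build_bfs(StepSpec(step_height=0.0), resolution=2.0)
    assert g.fluid_mask.all()


def test_bfs_nonpositive_lengths_raise():
    with pytest.raises(GeometryError):
        build_bfs(StepSpec(downstream_length=-1.0), 2.0)


def test_wall_faces_straight_channel_count_and_normals():
    g = make_channel(ny=8, nx=30)
    wf = classify_wall_faces(g)
    assert len(wf) == 2 * g.nx                  # top + bottom rows only
    assert np.allclose(np.linalg.norm(wf.normal, axis=1), 1.0)


def test_wall_faces_bfs_include_step_riser():
    g = build_bfs(StepSpec(), resolution=2.0)
    wf = g.wall_faces
    # riser: vertical wall faces (direction W) at the expansion corner
    riser = (wf.direction == W) & np.isclose(wf.x, g.step_info["x"])
    assert riser.sum() == g.ny - g.step_info["j_step"]
    assert np.allclose(wf.normal[riser], [1.0, 0.0])


def test_disconnected_fluid_raises():
    fm = np.zeros((6, 10), dtype=bool)
    fm[1:3, :] = True
    fm[5:6, :] = True                           # orphaned strip
    from thromboflow.grid import StructuredGrid
    with pytest.raises(GeometryError):
        StructuredGrid(nx=10, ny=6, dx=1e-3, dy=1e-3, fluid_mask=fm)


def test_arch_faces_near_inlet_only():
    g = build_phantom(PhantomSpec.canonical("C1"), 1.0)
    wf = g.wall_faces
    assert wf.is_arch.any()
    assert (wf.x[wf.is_arch] < g.arch_extent).all()
    assert (wf.x[~wf.is_arch] >= g.arch_extent).all()
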