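"""Structured 2-D computational domains.

Two families of geometry are supported:

* idealised aortic-dissection *phantoms* — a true lumen (TL) channel running
  the full vessel length, a blind false-lumen (FL) pocket alongside it, and a
  solid dissection flap separating the two, pierced by one or two tear
  openings;
* the *backward-facing step* (BFS) channel used as the thrombosis benchmark,
  in planar or axisymmetric form.

Walls are represented stair-stepped (voxelised) on a Cartesian cell-centred
grid.  Every solid/fluid interface is classified into wall faces with an
outward normal pointing into the fluid; phantom walls near the inlet can be
tagged as "arch" walls, which receive zero-flux species conditions instead of
adhesion/coagulant conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "StepSpec",
    "StructuredGrid",
    "WallFaces",
    "build_phantom",
    "build_bfs",
    "classify_wall_faces",
    "W", "E", "S", "N",
    "INTERIOR", "WALL", "INLET", "OUTLET", "AXIS",
]

# face direction codes (per-cell): west, east, south, north
W, E, S, N = 0, 1, 2, 3
_DJ = (0, 0, -1, 1)
_DI = (-1, 1, 0, 0)
# unit vector of each direction (pointing out of the cell)
_DIRVEC = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, -1.0], [0.0, 1.0]])

# face kind codes
INTERIOR, WALL, INLET, OUTLET, AXIS = 0, 1, 2, 3, 4


class GeometryError(ValueError):
    """Raised for degenerate or under-resolved geometry specifications."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of an idealised dissection phantom.

    Lengths are in millimetres, measured from the inlet.  Tear diameters of
    the canonical models follow the published configurations (10, 5 or
    20 mm); the remaining dimensions are reconstructions chosen to match the
    qualitative aspect of the published figures and are fully configurable.
    """

    n_tears: int
    proximal_tear_diameter: Optional[float] = None
    distal_tear_diameter: Optional[float] = None
    tear_axial_positions: tuple = ()
    true_lumen_width: float = 20.0
    false_lumen_width: float = 15.0
    flap_thickness: float = 2.0
    total_length: float = 300.0
    arch_region_extent: float = 45.0
    dissection_start: float = 60.0
    dissection_end: float = 260.0

    @classmethod
    def canonical(cls, name: str) -> "PhantomSpec":
        """Return one of the six canonical tear configurations C1..C6."""
        name = name.upper()
        table = {
            # (n, PT diameter, DT diameter, tear centres)
            "C1": (1, 10.0, None, (75.0,)),
            "C2": (1, None, 10.0, (245.0,)),
            "C3": (2, 10.0, 5.0, (75.0, 160.0)),   # re-entry tear mid-section
            "C4": (2, 10.0, 5.0, (75.0, 245.0)),
            "C5": (2, 10.0, 10.0, (75.0, 245.0)),
            "C6": (2, 20.0, 10.0, (75.0, 245.0)),
        }
        if name not in table:
            raise KeyError(f"unknown phantom model {name!r}")
        n, pt, dt, pos = table[name]
        return cls(n_tears=n, proximal_tear_diameter=pt,
                   distal_tear_diameter=dt, tear_axial_positions=pos)

    # -- helpers ---------------------------------------------------------
    def tears(self) -> list:
        """List of (label, centre_mm, diameter_mm) for the present tears."""
        out = []
        diams = []
        if self.n_tears == 1:
            if self.proximal_tear_diameter is not None:
                diams = [("proximal", self.proximal_tear_diameter)]
            else:
                diams = [("distal", self.distal_tear_diameter)]
        else:
            diams = [("proximal", self.proximal_tear_diameter),
                     ("distal", self.distal_tear_diameter)]
        if len(self.tear_axial_positions) != len(diams):
            raise GeometryError("tear_axial_positions length does not match n_tears")
        return [(lab, pos, d) for (lab, d), pos in zip(diams, self.tear_axial_positions)]

    def validate(self) -> None:
        if self.n_tears not in (1, 2):
            raise GeometryError("n_tears must be 1 or 2")
        for v, nm in [(self.true_lumen_width, "true_lumen_width"),
                      (self.false_lumen_width, "false_lumen_width"),
                      (self.flap_thickness, "flap_thickness"),
                      (self.total_length, "total_length")]:
            if v is None or v <= 0:
                raise GeometryError(f"{nm} must be positive")
        if not 0 <= self.dissection_start < self.dissection_end <= self.total_length:
            raise GeometryError("dissected segment must lie inside the vessel")
        tears = self.tears()
        for lab, pos, d in tears:
            if d is None or d <= 0:
                raise GeometryError(f"{lab} tear diameter must be positive")
            if pos - d / 2 < self.dissection_start or pos + d / 2 > self.dissection_end:
                raise GeometryError(f"{lab} tear does not fit on the flap segment")
        if len(tears) == 2:
            (l0, p0, d0), (l1, p1, d1) = tears
            if min(p0, p1) + (d0 if p0 < p1 else d1) / 2 > max(p0, p1) - (d1 if p0 < p1 else d0) / 2:
                raise GeometryError("tear openings overlap")


@dataclass(frozen=True)
class StepSpec:
    """Backward-facing-step channel (dimensions in mm).

    ``channel_height_upstream`` is the upstream bore (the tube diameter in
    axisymmetric mode); the downstream bore is the upstream bore plus the
    step height (planar) or plus twice the step height in diameter
    (axisymmetric).  Defaults reproduce the benchmark tube: a 10 mm bore
    expanding over a 2.5 mm step, giving a 1.5 expansion ratio and a step
    Reynolds number of ~120 at the benchmark flow rate.
    """

    channel_height_upstream: float = 10.0
    step_height: float = 2.5
    upstream_length: float = 20.0
    downstream_length: float = 60.0

    def validate(self) -> None:
        for v, nm in [(self.channel_height_upstream, "channel_height_upstream"),
                      (self.upstream_length, "upstream_length"),
                      (self.downstream_length, "downstream_length")]:
            if v <= 0:
                raise GeometryError(f"{nm} must be positive")
        if self.step_height < 0:
            raise GeometryError("step_height must be non-negative")


@dataclass
class WallFaces:
    """Flat arrays describing every solid/fluid interface face.

    ``cell`` indexes the adjacent *fluid* cell (linear fluid index),
    ``direction`` is the per-cell face code (W/E/S/N), ``normal`` the unit
    outward normal pointing from the wall into the fluid, and ``is_arch``
    marks aortic-arch faces (zero species flux).
    """

    cell: np.ndarray
    direction: np.ndarray
    area: np.ndarray
    dist: np.ndarray          # cell-centre to face distance
    x: np.ndarray
    y: np.ndarray
    normal: np.ndarray        # (n, 2), unit, pointing into the fluid
    is_arch: np.ndarray

    def __len__(self) -> int:
        return self.cell.size


@dataclass
class StructuredGrid:
    """Cell-centred Cartesian grid with fluid mask and boundary metadata.

    Cell centres sit at ``x=(i+1/2)dx``, ``y=(j+1/2)dy`` with ``j`` the
    cross-stream (or radial) index.  In axisymmetric mode ``y`` is the radial
    coordinate and the ``j=0`` row borders the symmetry axis.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    fluid_mask: np.ndarray
    axisymmetric: bool = False
    arch_extent: float = 0.0          # walls with x < arch_extent are "arch"
    tear_openings: list = field(default_factory=list)
    region_masks: dict = field(default_factory=dict)
    step_info: dict = field(default_factory=dict)

    # derived fields, filled by _finalize
    ids: np.ndarray = None
    n_fluid: int = 0
    jj: np.ndarray = None
    ii: np.ndarray = None
    nb: np.ndarray = None             # (4, n_fluid) neighbour fluid ids, -1 outside
    face_kind: np.ndarray = None      # (4, n_fluid)
    face_area: np.ndarray = None      # (4, n_fluid)
    face_dist: np.ndarray = None      # (4, n_fluid) centre-to-centre / centre-to-face
    volume: np.ndarray = None         # (n_fluid,)
    r_center: np.ndarray = None       # (n_fluid,), 1.0 in planar mode
    wall_faces: WallFaces = None
    inlet_cells: np.ndarray = None
    outlet_cells: np.ndarray = None

    def __post_init__(self):
        self._finalize()

    # ------------------------------------------------------------------
    def _finalize(self) -> None:
        fm = self.fluid_mask
        ny, nx = fm.shape
        assert (ny, nx) == (self.ny, self.nx)
        if not fm.any():
            raise GeometryError("grid has no fluid cells")

        ids = np.full((ny, nx), -1, dtype=np.int64)
        jj, ii = np.nonzero(fm)
        n = jj.size
        ids[jj, ii] = np.arange(n)
        self.ids, self.jj, self.ii, self.n_fluid = ids, jj, ii, n

        # fluid connectivity: all fluid must form one component reaching the inlet
        lab, nlab = ndimage.label(fm)
        if nlab != 1:
            raise GeometryError(f"fluid region is disconnected ({nlab} components)")

        nb = np.full((4, n), -1, dtype=np.int64)
        kind = np.full((4, n), WALL, dtype=np.int8)
        area = np.zeros((4, n))
        dist = np.zeros((4, n))

        if self.axisymmetric:
            rc = (jj + 0.5) * self.dy
            r_s = jj * self.dy
            r_n = (jj + 1) * self.dy
            a_we = rc * self.dy
            a_s = r_s * self.dx
            a_n = r_n * self.dx
            vol = rc * self.dx * self.dy
        else:
            rc = np.ones(n)
            a_we = np.full(n, self.dy)
            a_s = np.full(n, self.dx)
            a_n = np.full(n, self.dx)
            vol = np.full(n, self.dx * self.dy)
        self.volume, self.r_center = vol, rc

        for d in range(4):
            nj, ni = jj + _DJ[d], ii + _DI[d]
            inside = (nj >= 0) & (nj < ny) & (ni >= 0) & (ni < nx)
            nb_d = np.where(inside, ids[nj % ny, ni % nx], -1)
            nb[d] = nb_d
            interior = nb_d >= 0
            kind[d, interior] = INTERIOR
            if d == W:
                kind[d, ii == 0] = INLET
            elif d == E:
                kind[d, ii == nx - 1] = OUTLET
            elif d == S and self.axisymmetric:
                kind[d, jj == 0] = AXIS
            area[d] = {W: a_we, E: a_we, S: a_s, N: a_n}[d]
            full = self.dx if d in (W, E) else self.dy
            dist[d] = np.where(interior, full, full / 2.0)

        self.nb, self.face_kind, self.face_area, self.face_dist = nb, kind, area, dist
        self.inlet_cells = np.nonzero(kind[W] == INLET)[0]
        self.outlet_cells = np.nonzero(kind[E] == OUTLET)[0]
        self.wall_faces = classify_wall_faces(self)

    # ------------------------------------------------------------------
    @property
    def x_centers(self) -> np.ndarray:
        return (self.ii + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (self.jj + 0.5) * self.dy

    def fluid_area(self) -> float:
        """Planar fluid area in m^2 (cell count times cell area)."""
        return float(self.n_fluid * self.dx * self.dy)

    def full(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-fluid-cell vector onto the full (ny, nx) rectangle."""
        out = np.full((self.ny, self.nx), fill, dtype=float)
        out[self.jj, self.ii] = vec
        return out

    def pack(self, arr2d: np.ndarray) -> np.ndarray:
        """Gather a full (ny, nx) array into a per-fluid-cell vector."""
        return np.asarray(arr2d, dtype=float)[self.jj, self.ii]

    def export_vtk(self, path, fields: dict) -> None:
        from . import vtkio
        vtkio.write_vtk(path, self, fields)


def classify_wall_faces(grid: StructuredGrid) -> WallFaces:
    """Enumerate every solid/fluid interface face exactly once.

    Returns the faces with unit outward normals pointing from the wall into
    the adjacent fluid cell.  Domain-boundary faces that are inlet, outlet or
    the symmetry axis are excluded.
    """
    d_idx, c_idx = np.nonzero(grid.face_kind == WALL)
    xf = (grid.ii[c_idx] + 0.5 + 0.5 * np.array(_DI)[d_idx]) * grid.dx
    yf = (grid.jj[c_idx] + 0.5 + 0.5 * np.array(_DJ)[d_idx]) * grid.dy
    normal = -_DIRVEC[d_idx]
    is_arch = (grid.arch_extent > 0) & (xf < grid.arch_extent)
    return WallFaces(
        cell=c_idx,
        direction=d_idx,
        area=grid.face_area[d_idx, c_idx],
        dist=grid.face_dist[d_idx, c_idx],
        x=xf,
        y=yf,
        normal=normal,
        is_arch=np.asarray(is_arch, dtype=bool),
    )


# ----------------------------------------------------------------------
def build_phantom(spec: PhantomSpec, resolution: float) -> StructuredGrid:
    """Build a dissection-phantom grid at ``resolution`` cells per mm.

    The true lumen spans the whole vessel length; the false lumen is a blind
    pocket alongside it covering the dissected segment, connected to the true
    lumen only through the tear openings in the flap.  Raises
    :class:`GeometryError` when the geometry is degenerate or the resolution
    cannot resolve the smallest tear with at least 4 cells.
    """
    spec.validate()
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    res = float(resolution)
    tears = spec.tears()
    smallest = min(d for _, _, d in tears)
    if smallest * res < 4:
        raise GeometryError(
            f"resolution {res} cells/mm resolves the {smallest} mm tear with "
            f"fewer than 4 cells")

    mm = 1e-3
    nx = int(round(spec.total_length * res))
    n_tl = int(round(spec.true_lumen_width * res))
    n_flap = max(1, int(round(spec.flap_thickness * res)))
    n_fl = int(round(spec.false_lumen_width * res))
    if n_fl < 2:
        raise GeometryError("false lumen under-resolved (needs >= 2 cells)")
    ny = n_tl + n_flap + n_fl
    dx = dy = mm / res

    fm = np.zeros((ny, nx), dtype=bool)
    fm[:n_tl, :] = True                                   # true lumen
    i0 = int(round(spec.dissection_start * res))
    i1 = int(round(spec.dissection_end * res))
    fm[n_tl + n_flap:, i0:i1] = True                      # false lumen pocket

    openings = []
    for lab, pos, d in tears:
        ia = int(np.floor((pos - d / 2) * res + 0.5))
        ib = ia + int(round(d * res))           # opening width exact in cells
        fm[n_tl:n_tl + n_flap, ia:ib] = True              # tear gap in flap
        openings.append({"label": lab, "i0": ia, "i1": ib,
                         "j_face": n_tl, "center_mm": pos, "diameter_mm": d})

    region = {
        "true_lumen": np.zeros((ny, nx), dtype=bool),
        "false_lumen": np.zeros((ny, nx), dtype=bool),
    }
    region["true_lumen"][:n_tl, :] = True
    region["false_lumen"][n_tl + n_flap:, i0:i1] = True

    return StructuredGrid(
        nx=nx, ny=ny, dx=dx, dy=dy, fluid_mask=fm, axisymmetric=False,
        arch_extent=spec.arch_region_extent * mm,
        tear_openings=openings, region_masks=region)


def build_bfs(spec: StepSpec, resolution: float,
              axisymmetric: bool = True) -> StructuredGrid:
    """Build the backward-facing-step grid at ``resolution`` cells per mm.

    In axisymmetric mode the grid spans the radius: the upstream tube of
    diameter ``channel_height_upstream`` expands by ``step_height`` in radius
    at ``x = upstream_length``; the ``j=0`` row borders the symmetry axis and
    the step sits on the outer wall.  In planar mode the full channel height
    is gridded and the step sits on the top wall.
    """
    spec.validate()
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    res = float(resolution)
    mm = 1e-3
    dx = dy = mm / res

    if axisymmetric:
        up = spec.channel_height_upstream / 2.0           # upstream radius
    else:
        up = spec.channel_height_upstream                 # upstream height
    n_up = int(round(up * res))
    n_step = int(round(spec.step_height * res))
    ny = n_up + n_step
    n_xup = int(round(spec.upstream_length * res))
    nx = n_xup + int(round(spec.downstream_length * res))

    fm = np.zeros((ny, nx), dtype=bool)
    fm[:n_up, :n_xup] = True          # upstream bore (axis/centre at j=0)
    fm[:, n_xup:] = True              # expanded downstream section

    step_info = {
        "x": n_xup * dx,              # streamwise position of the riser (m)
        "height": n_step * dy,        # resolved step height (m)
        "outer_radius": ny * dy,      # outer wall position (m)
        "i_step": n_xup,
        "j_step": n_up,
    }
    return StructuredGrid(nx=nx, ny=ny, dx=dx, dy=dy, fluid_mask=fm,
                          axisymmetric=axisymmetric, step_info=step_info)
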