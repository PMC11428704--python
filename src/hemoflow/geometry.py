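"""Synthetic vessel geometries and structured meshing.

Patient CT-derived 3-D aortas are replaced by desk-scale 2-D domains:

* ``straight`` — an (optionally tapered) axisymmetric tube, the oracle
  geometry for Poiseuille/Womersley verification;
* ``arch`` — a planar curved channel (annular sector) standing in for the
  aortic arch;
* ``dissected`` — a planar two-lumen channel: a true lumen fed by the
  inlet, a false lumen sealed at the inlet end, and an intimal septum
  separating them except at one or more tear openings.

Meshes are structured quadrilateral grids with tagged boundary faces
(inlet / outlet / wall / septum / axis).  Specs are in millimetres;
mesh coordinates are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import presets

__all__ = [
    "VesselSpec",
    "StructuredMesh",
    "BoundaryFace",
    "build_vessel",
    "refine",
    "mesh_convergence_report",
    "PRE_AD",
    "POST_AD",
]

MM = 1e-3

DiameterLike = Union[float, Tuple[float, float]]


def _as_pair(d: DiameterLike) -> Tuple[float, float]:
    if np.isscalar(d):
        return (float(d), float(d))
    a, b = d
    return (float(a), float(b))


@dataclass(frozen=True)
class VesselSpec:
    """Geometric specification of a synthetic vessel (all lengths in mm).

    ``true_lumen_diameter``/``false_lumen_diameter`` may be scalars or
    (inlet, outlet) pairs for linearly tapered lumens.  ``tear_positions``
    is a list of (arc-length start, opening length) pairs along the
    septum; the dissected kind requires at least one tear so the false
    lumen is connected to the inlet flow.
    """

    kind: str = "straight"
    inlet_diameter: float = 20.0
    outlet_diameter: Optional[float] = None
    length: float = 100.0
    bend_angle: float = 0.0
    true_lumen_diameter: DiameterLike = 0.0
    false_lumen_diameter: DiameterLike = 0.0
    septum_thickness: float = presets.DEFAULT_SEPTUM_THICKNESS_MM
    tear_positions: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "arch", "dissected"):
            raise ValueError(f"unknown vessel kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.outlet_diameter is None:
            object.__setattr__(self, "outlet_diameter", self.inlet_diameter)
        if self.kind in ("straight", "arch"):
            if self.inlet_diameter <= 0 or self.outlet_diameter <= 0:
                raise ValueError("diameters must be positive")
        if self.kind == "arch" and not 0 < self.bend_angle <= 360:
            raise ValueError("arch requires bend_angle in (0, 360] degrees")
        if self.kind == "dissected":
            tl = _as_pair(self.true_lumen_diameter)
            fl = _as_pair(self.false_lumen_diameter)
            if min(tl) <= 0 or min(fl) <= 0:
                raise ValueError("dissected lumen diameters must be positive")
            if self.septum_thickness <= 0:
                raise ValueError("septum_thickness must be positive")
            if len(self.tear_positions) < 1:
                raise ValueError(
                    "dissected vessel requires at least one tear so both "
                    "lumens connect to the inlet flow"
                )
            for pos, opening in self.tear_positions:
                if opening <= 0:
                    raise ValueError("tear opening must be positive")
                if pos < 0 or pos + opening > self.length:
                    raise ValueError(
                        f"tear [{pos}, {pos + opening}] mm lies outside the "
                        f"vessel (length {self.length} mm)"
                    )

    @property
    def is_tapered(self) -> bool:
        if self.kind == "dissected":
            tl = _as_pair(self.true_lumen_diameter)
            fl = _as_pair(self.false_lumen_diameter)
            return tl[0] != tl[1] or fl[0] != fl[1]
        return self.inlet_diameter != self.outlet_diameter


#: Pre-dissection aorta: straight tapered tube, ascending -> descending.
PRE_AD = VesselSpec(
    kind="straight",
    inlet_diameter=presets.PRE_AD_ASCENDING_DIAMETER_MM,
    outlet_diameter=presets.PRE_AD_DESCENDING_DIAMETER_MM,
    length=presets.DEFAULT_VESSEL_LENGTH_MM,
)

#: Post-dissection aorta: two-lumen channel with the measured true/false
#: lumen diameters at the ascending (inlet) and descending (outlet) ends.
POST_AD = VesselSpec(
    kind="dissected",
    length=presets.DEFAULT_VESSEL_LENGTH_MM,
    true_lumen_diameter=(presets.POST_AD_TRUE_ASCENDING_MM,
                         presets.POST_AD_TRUE_DESCENDING_MM),
    false_lumen_diameter=(presets.POST_AD_FALSE_ASCENDING_MM,
                          presets.POST_AD_FALSE_DESCENDING_MM),
    septum_thickness=presets.DEFAULT_SEPTUM_THICKNESS_MM,
    tear_positions=(presets.DEFAULT_TEAR_MM,),
)


@dataclass(frozen=True)
class BoundaryFace:
    """One tagged boundary face of a cell: (cell i, cell j, side, tag).

    ``side`` is one of 'W', 'E', 'S', 'N' (west = -x, east = +x,
    south = -y, north = +y).
    """

    i: int
    j: int
    side: str
    tag: str


@dataclass(frozen=True)
class StructuredMesh:
    """Structured quadrilateral mesh with tagged boundaries.

    ``nodes`` has shape (ni+1, nj+1, 2) in metres, x along the flow axis
    and y across (the radial coordinate when ``axisymmetric``).  ``fluid``
    marks flow cells; ``septum`` marks the solid intimal-flap cells of a
    dissected domain (a subset of ``~fluid``).  ``inlet_open`` marks which
    j-columns of the i = 0 face are flow inlets (the false lumen of a
    dissected domain is sealed there).
    """

    nodes: np.ndarray
    fluid: np.ndarray
    septum: np.ndarray
    axisymmetric: bool
    inlet_open: np.ndarray
    spec: Optional[VesselSpec] = None

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        fluid = np.asarray(self.fluid, dtype=bool)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "fluid", fluid)
        object.__setattr__(self, "septum", np.asarray(self.septum, dtype=bool))
        object.__setattr__(self, "inlet_open",
                           np.asarray(self.inlet_open, dtype=bool))
        if nodes.ndim != 3 or nodes.shape[2] != 2:
            raise ValueError("nodes must have shape (ni+1, nj+1, 2)")
        if fluid.shape != (nodes.shape[0] - 1, nodes.shape[1] - 1):
            raise ValueError("fluid mask shape does not match nodes")

    @property
    def shape(self) -> Tuple[int, int]:
        """(ni, nj) cell counts of the structured grid."""
        return self.fluid.shape

    @property
    def n_cells(self) -> int:
        """Number of fluid cells."""
        return int(np.count_nonzero(self.fluid))

    @property
    def is_rectilinear(self) -> bool:
        """True when nodes form a uniform tensor-product grid (the only
        layout the flow solver supports)."""
        x = self.nodes[:, :, 0]
        y = self.nodes[:, :, 1]
        if not (np.allclose(x, x[:, :1]) and np.allclose(y, y[:1, :])):
            return False
        dx = np.diff(x[:, 0])
        dy = np.diff(y[0, :])
        return (np.allclose(dx, dx[0], rtol=1e-9, atol=0)
                and np.allclose(dy, dy[0], rtol=1e-9, atol=0))

    @property
    def x_faces(self) -> np.ndarray:
        return self.nodes[:, 0, 0]

    @property
    def y_faces(self) -> np.ndarray:
        return self.nodes[0, :, 1]

    def cell_centers(self) -> np.ndarray:
        """(ni, nj, 2) bilinear cell centroids."""
        n = self.nodes
        return 0.25 * (n[:-1, :-1] + n[1:, :-1] + n[:-1, 1:] + n[1:, 1:])

    def cell_areas(self) -> np.ndarray:
        """Signed quadrilateral areas (shoelace); positive for valid cells."""
        n = self.nodes
        a = n[:-1, :-1]
        b = n[1:, :-1]
        c = n[1:, 1:]
        d = n[:-1, 1:]

        def cross(p, q):
            return p[..., 0] * q[..., 1] - p[..., 1] * q[..., 0]

        return 0.5 * (cross(b - a, c - a) + cross(c - a, d - a))

    def boundary_faces(self) -> List[BoundaryFace]:
        """Every boundary face of every fluid cell with exactly one tag."""
        ni, nj = self.shape
        faces: List[BoundaryFace] = []
        solid = ~self.fluid
        for i in range(ni):
            for j in range(nj):
                if not self.fluid[i, j]:
                    continue
                # west
                if i == 0:
                    tag = "inlet" if self.inlet_open[j] else "wall"
                    faces.append(BoundaryFace(i, j, "W", tag))
                elif solid[i - 1, j]:
                    faces.append(BoundaryFace(
                        i, j, "W", "septum" if self.septum[i - 1, j] else "wall"))
                # east
                if i == ni - 1:
                    faces.append(BoundaryFace(i, j, "E", "outlet"))
                elif solid[i + 1, j]:
                    faces.append(BoundaryFace(
                        i, j, "E", "septum" if self.septum[i + 1, j] else "wall"))
                # south
                if j == 0:
                    faces.append(BoundaryFace(
                        i, j, "S", "axis" if self.axisymmetric else "wall"))
                elif solid[i, j - 1]:
                    faces.append(BoundaryFace(
                        i, j, "S", "septum" if self.septum[i, j - 1] else "wall"))
                # north
                if j == nj - 1:
                    faces.append(BoundaryFace(i, j, "N", "wall"))
                elif solid[i, j + 1]:
                    faces.append(BoundaryFace(
                        i, j, "N", "septum" if self.septum[i, j + 1] else "wall"))
        return faces

    def validate(self) -> None:
        """Audit the mesh: positive cell areas, finite nodes, tag coverage."""
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("mesh nodes contain non-finite coordinates")
        areas = self.cell_areas()
        if np.any(areas[self.fluid] <= 0):
            raise ValueError("mesh contains non-positive cell Jacobians")
        if self.n_cells == 0:
            raise ValueError("mesh has no fluid cells")
        tags = {f.tag for f in self.boundary_faces()}
        if "inlet" not in tags or "outlet" not in tags:
            raise ValueError("mesh lacks inlet/outlet boundary tags")


def _resolve_counts(width_mm: float, dy_mm: float, minimum: int = 1) -> int:
    return max(minimum, int(round(width_mm / dy_mm)))


def build_vessel(spec: VesselSpec, resolution: int = 16) -> StructuredMesh:
    """Mesh a vessel spec with ``resolution`` cells across the inlet diameter.

    The straight tube is meshed axisymmetrically over [0, R]; arch and
    dissected kinds are planar.  Dissected septum and lumen widths are
    snapped to whole cells (within one cell width of the spec); a septum
    thinner than one cell at the chosen resolution is rejected.
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8 cells across the diameter")
    if spec.kind == "straight":
        return _build_straight(spec, resolution)
    if spec.kind == "arch":
        return _build_arch(spec, resolution)
    return _build_dissected(spec, resolution)


def _build_straight(spec: VesselSpec, resolution: int) -> StructuredMesh:
    nj = max(4, resolution // 2)  # cells across the radius
    r_in = spec.inlet_diameter / 2.0 * MM
    r_out = spec.outlet_diameter / 2.0 * MM
    length = spec.length * MM
    dy = r_in / nj
    ni = max(4, int(round(length / dy)))
    x = np.linspace(0.0, length, ni + 1)
    frac = np.linspace(0.0, 1.0, nj + 1)
    radius = r_in + (r_out - r_in) * (x / length)
    nodes = np.empty((ni + 1, nj + 1, 2))
    nodes[:, :, 0] = x[:, None]
    nodes[:, :, 1] = radius[:, None] * frac[None, :]
    fluid = np.ones((ni, nj), dtype=bool)
    return StructuredMesh(
        nodes=nodes, fluid=fluid, septum=np.zeros_like(fluid),
        axisymmetric=True, inlet_open=np.ones(nj, dtype=bool), spec=spec)


def _build_arch(spec: VesselSpec, resolution: int) -> StructuredMesh:
    nj = resolution
    d_in = spec.inlet_diameter * MM
    d_out = spec.outlet_diameter * MM
    length = spec.length * MM
    angle = np.deg2rad(spec.bend_angle)
    rc = length / angle  # centreline radius
    if rc <= max(d_in, d_out) / 2.0:
        raise ValueError("bend too tight: channel self-intersects")
    dy = d_in / nj
    ni = max(4, int(round(length / dy)))
    theta = np.linspace(0.0, angle, ni + 1)
    d = d_in + (d_out - d_in) * theta / angle
    frac = np.linspace(0.0, 1.0, nj + 1)
    # j runs outer -> inner radius so the (i, j) cell orientation stays
    # positive in the (x, y) embedding
    rho = (rc + d[:, None] / 2.0) - d[:, None] * frac[None, :]
    nodes = np.empty((ni + 1, nj + 1, 2))
    nodes[:, :, 0] = rho * np.sin(theta)[:, None]
    nodes[:, :, 1] = rc - rho * np.cos(theta)[:, None]
    fluid = np.ones((ni, nj), dtype=bool)
    return StructuredMesh(
        nodes=nodes, fluid=fluid, septum=np.zeros_like(fluid),
        axisymmetric=False, inlet_open=np.ones(nj, dtype=bool), spec=spec)


def _build_dissected(spec: VesselSpec, resolution: int) -> StructuredMesh:
    tl = _as_pair(spec.true_lumen_diameter)
    fl = _as_pair(spec.false_lumen_diameter)
    length = spec.length * MM
    dy_mm = tl[0] / resolution
    n_t = resolution
    n_s = int(round(spec.septum_thickness / dy_mm))
    if n_s < 1:
        raise ValueError(
            f"resolution {resolution} too coarse to resolve the "
            f"{spec.septum_thickness} mm septum (cell {dy_mm:.3g} mm)"
        )
    n_f = _resolve_counts(fl[0], dy_mm, minimum=2)
    nj = n_t + n_s + n_f
    ni = max(4, int(round(spec.length / dy_mm)))
    x = np.linspace(0.0, length, ni + 1)

    # per-station band widths (m), linearly tapered; septum constant
    w_t = (tl[0] + (tl[1] - tl[0]) * x / length) * MM
    w_s = np.full(ni + 1, spec.septum_thickness * MM)
    w_f = (fl[0] + (fl[1] - fl[0]) * x / length) * MM

    nodes = np.empty((ni + 1, nj + 1, 2))
    nodes[:, :, 0] = x[:, None]
    for i in range(ni + 1):
        y = np.concatenate([
            np.linspace(0.0, w_t[i], n_t + 1),
            w_t[i] + np.linspace(0.0, w_s[i], n_s + 1)[1:],
            w_t[i] + w_s[i] + np.linspace(0.0, w_f[i], n_f + 1)[1:],
        ])
        nodes[i, :, 1] = y

    fluid = np.ones((ni, nj), dtype=bool)
    septum = np.zeros((ni, nj), dtype=bool)
    septum[:, n_t:n_t + n_s] = True
    # open the tears
    xc = 0.5 * (x[:-1] + x[1:]) / MM  # cell-centre arc positions, mm
    for pos, opening in spec.tear_positions:
        in_tear = (xc >= pos) & (xc <= pos + opening)
        if not np.any(in_tear):
            raise ValueError(
                f"tear at {pos} mm (opening {opening} mm) is narrower than "
                "one cell at this resolution"
            )
        septum[in_tear, n_t:n_t + n_s] = False
    fluid[septum] = False

    inlet_open = np.zeros(nj, dtype=bool)
    inlet_open[:n_t] = True  # only the true lumen is fed by the inlet
    return StructuredMesh(
        nodes=nodes, fluid=fluid, septum=septum, axisymmetric=False,
        inlet_open=inlet_open, spec=spec)


def _linear_refine(arr: np.ndarray, factor: int, axis: int) -> np.ndarray:
    """Insert factor-1 linear interpolants between consecutive entries."""
    arr = np.moveaxis(arr, axis, 0)
    n = arr.shape[0] - 1
    out = np.empty((n * factor + 1,) + arr.shape[1:], dtype=arr.dtype)
    out[::factor] = arr
    for k in range(1, factor):
        out[k::factor] = ((factor - k) * arr[:-1] + k * arr[1:]) / factor
    return np.moveaxis(out, 0, axis)


def refine(mesh: StructuredMesh, factor: int) -> StructuredMesh:
    """Split every cell ``factor`` times per direction, preserving tags.

    Node insertion is bilinear within each original cell, so refining
    twice by 2 reproduces a single refinement by 4 (to round-off).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise ValueError("refinement factor must be an integer >= 2")
    nodes = _linear_refine(_linear_refine(mesh.nodes, factor, 0), factor, 1)
    ones = np.ones((factor, factor), dtype=bool)
    fluid = np.kron(mesh.fluid, ones)
    septum = np.kron(mesh.septum, ones)
    inlet_open = np.repeat(mesh.inlet_open, factor)
    return StructuredMesh(nodes=nodes, fluid=fluid, septum=septum,
                          axisymmetric=mesh.axisymmetric,
                          inlet_open=inlet_open, spec=mesh.spec)


def mesh_convergence_report(solutions: Sequence[Tuple[StructuredMesh, object]],
                            rheology=None) -> pd.DataFrame:
    """Mesh-convergence table over successive refinement levels.

    ``solutions`` is a list of (mesh, FlowState-or-FlowSeries) pairs for
    the same vessel spec at increasing resolution.  Returns one row per
    level with the fluid cell count, maximum wall shear stress, maximum
    pressure and maximum velocity magnitude, plus the relative change of
    each quantity from the previous level.
    """
    from . import solver as _solver
    from .rheology import RheologyParams

    if len(solutions) < 2:
        raise ValueError("need at least two refinement levels")
    specs = {id(m.spec) if m.spec is None else m.spec
             for m, _ in solutions}
    if len({m.axisymmetric for m, _ in solutions}) > 1 or len(specs) > 1:
        raise ValueError("all levels must mesh the same vessel spec")
    cells = [m.n_cells for m, _ in solutions]
    if any(b <= a for a, b in zip(cells, cells[1:])):
        if len(set(cells)) != 1:  # identical duplicated levels are allowed
            raise ValueError("cell counts must be non-decreasing across levels")
    rheology = rheology or RheologyParams()

    rows = []
    for mesh, sol in solutions:
        series = _solver.as_series(sol)
        wss = _solver.wall_shear_stress(series, mesh, rheology)
        wss_max = float(np.max(np.linalg.norm(wss.vectors, axis=-1)))
        p_max = float(np.max(series.p[:, mesh.fluid]))
        speed = _solver.cell_speed(series, mesh)
        v_max = float(np.max(speed[:, mesh.fluid]))
        rows.append({"cells": mesh.n_cells, "wss_max": wss_max,
                     "p_max": p_max, "v_max": v_max})
    table = pd.DataFrame(rows)
    for col in ("wss_max", "p_max", "v_max"):
        prev = table[col].shift(1)
        denom = prev.where(prev.abs() > 0, np.nan)
        table[f"{col}_rel_change"] = ((table[col] - prev) / denom).abs()
    return table
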