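"""Idealized dissected-aorta cross-section geometry and meshing.

The unloaded cross-section is an annulus of lumen radius ``R``.  Over the
dissected sector (a fraction ``f`` of the circumference, 50-60 % for the
dissections considered) the wall is split into an inner *intimal flap* layer
and an outer *false-lumen (FL) wall* layer; the remaining sector is the
intact *true-lumen (TL) wall*.  The flap sits on its original mural arc, in
zero-gap apposition against the FL wall (configurable initial gap), and all
three layers merge at the two tear-edge junctions.

Meshing is structured polar: a ring of bilinear quadrilateral columns with an
inner ladder (flap thickness, at least two element rows so the flap can bend)
and an outer ladder (FL wall thickness over the dissected sector, remaining
TL-wall thickness elsewhere, with a short geometric transition at the
junctions).  Interface nodes between flap and FL wall are duplicated so the
pair can separate and re-contact.  Boundary-edge sets are oriented with the
solid on the left of each edge, so the outward normal of edge ``(a, b)`` is
the edge vector rotated -90 degrees; pressure loading and contact rely on
this convention.

The unloaded lumen radius is an assumption (not a measured quantity):
defaults are 9 mm (mid) and 7 mm (distal) inner radius, typical porcine
descending thoracic dimensions consistent with the distal aorta being
smaller; every result record flags the value used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

LAYERS = ("flap", "fl_wall", "tl_wall")
FLAP, FL_WALL, TL_WALL = 0, 1, 2

DEFAULT_INNER_RADIUS_MM = {"mid": 9.0, "distal": 7.0}


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class DissectionGeometry:
    """Cross-section description of a dissected aorta.

    ``flap_fraction`` is flap circumference / aortic circumference; ``None``
    selects the intact single-layer ring mode (verification geometry).
    """

    region: str = "mid"
    inner_radius_mm: float = 9.0
    flap_fraction: float | None = 0.55
    flap_thickness_mm: float = 0.58
    fl_wall_thickness_mm: float = 1.3
    tl_wall_thickness_mm: float = 1.76
    symmetry: bool = True
    initial_gap_mm: float = 0.0
    fraction_band: tuple = (0.5, 0.6)

    def __post_init__(self):
        if self.flap_fraction is not None:
            f = self.flap_fraction
            if not (0.0 < f < 1.0):
                raise GeometryError(f"flap_fraction must lie in (0, 1); got {f}")
            lo, hi = self.fraction_band
            if not (lo - 1e-12 <= f <= hi + 1e-12):
                raise GeometryError(
                    f"flap_fraction {f} outside configured band [{lo}, {hi}]"
                )
            for name in ("flap_thickness_mm", "fl_wall_thickness_mm"):
                if getattr(self, name) <= 0:
                    raise GeometryError(f"{name} must be > 0")
        if self.tl_wall_thickness_mm <= 0:
            raise GeometryError("tl_wall_thickness_mm must be > 0")
        if self.initial_gap_mm < 0:
            raise GeometryError("initial_gap_mm must be >= 0")
        tmax = max(self.tl_wall_thickness_mm,
                   (self.flap_thickness_mm + self.fl_wall_thickness_mm)
                   if self.flap_fraction is not None else 0.0)
        if self.inner_radius_mm <= tmax:
            raise GeometryError("inner radius must exceed the largest wall thickness")

    @property
    def intact(self) -> bool:
        return self.flap_fraction is None

    @classmethod
    def for_region(cls, region: str, flap_thickness_mm: float,
                   fl_wall_thickness_mm: float, tl_wall_thickness_mm: float,
                   **kw) -> "DissectionGeometry":
        kw.setdefault("inner_radius_mm", DEFAULT_INNER_RADIUS_MM[region])
        return cls(region=region, flap_thickness_mm=flap_thickness_mm,
                   fl_wall_thickness_mm=fl_wall_thickness_mm,
                   tl_wall_thickness_mm=tl_wall_thickness_mm, **kw)

    @classmethod
    def intact_ring(cls, inner_radius_mm: float, wall_thickness_mm: float,
                    symmetry: bool = True) -> "DissectionGeometry":
        return cls(region="ring", inner_radius_mm=inner_radius_mm,
                   flap_fraction=None, tl_wall_thickness_mm=wall_thickness_mm,
                   symmetry=symmetry)


@dataclass
class CrossSectionMesh:
    """Quadrilateral cross-section mesh with layer tags and boundary-edge sets.

    ``boundary_sets`` maps set names (tl_lumen_surface, flap_tl_side,
    flap_fl_side, fl_wall_inner, outer_surface, symmetry_plane) to arrays of
    oriented node-pair edges (solid on the left).
    """

    nodes: np.ndarray          # (N, 2) reference coordinates, mm
    elems: np.ndarray          # (Ne, 4) CCW connectivity
    layer: np.ndarray          # (Ne,) codes into LAYERS
    boundary_sets: dict
    h: float
    geometry: DissectionGeometry

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    def set_nodes(self, name: str) -> np.ndarray:
        """Unique node ids in a boundary set, in edge order."""
        edges = self.boundary_sets[name]
        if len(edges) == 0:
            return np.empty(0, dtype=int)
        ids = np.concatenate([edges[:, 0], edges[-1:, 1]])
        return np.unique(ids) if name == "symmetry_plane" else np.array(
            list(dict.fromkeys(ids.tolist()))
        )

    def element_areas(self) -> np.ndarray:
        x = self.nodes[self.elems]  # (Ne,4,2)
        x1 = np.roll(x, -1, axis=1)
        return 0.5 * np.abs(np.sum(x[:, :, 0] * x1[:, :, 1] - x1[:, :, 0] * x[:, :, 1], axis=1))

    def layer_areas(self) -> dict:
        a = self.element_areas()
        return {name: float(a[self.layer == code].sum())
                for code, name in enumerate(LAYERS)}

    def min_jacobian(self) -> float:
        """Minimum corner Jacobian (signed, CCW positive) over all elements."""
        x = self.nodes[self.elems]
        jmin = np.inf
        for c in range(4):
            p0 = x[:, c]
            e1 = x[:, (c + 1) % 4] - p0
            e2 = x[:, (c - 1) % 4] - p0
            cr = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
            jmin = min(jmin, np.min(cr))
        return float(jmin)

    def validate(self) -> None:
        if self.min_jacobian() <= 0:
            raise GeometryError("mesh contains inverted or degenerate elements")
        sym = self.boundary_sets.get("symmetry_plane")
        if sym is not None and len(sym):
            ids = np.unique(sym)
            if np.max(np.abs(self.nodes[ids, 0])) > 1e-9:
                raise GeometryError("symmetry-plane nodes must lie on x = 0")


def _ring_angles(geom: DissectionGeometry, h: float):
    """Column angles; returns (theta array, junction index or None)."""
    r_mid = geom.inner_radius_mm + 0.5 * geom.tl_wall_thickness_mm
    if geom.symmetry:
        th_lo, th_hi = -np.pi / 2, np.pi / 2
    else:
        th_lo, th_hi = -np.pi / 2, 3 * np.pi / 2
    if geom.intact:
        n = max(8, int(np.ceil((th_hi - th_lo) * r_mid / h)))
        return np.linspace(th_lo, th_hi, n + 1), None
    span = np.pi * geom.flap_fraction if geom.symmetry else 2 * np.pi * geom.flap_fraction
    if geom.symmetry:
        th_j = np.pi / 2 - span
        n_tl = max(4, int(np.ceil((th_j - th_lo) * r_mid / h)))
        n_fl = max(6, int(np.ceil((np.pi / 2 - th_j) * r_mid / h)))
        th = np.concatenate([np.linspace(th_lo, th_j, n_tl + 1),
                             np.linspace(th_j, np.pi / 2, n_fl + 1)[1:]])
        return th, n_tl
    # full model: dissected sector centered on +y, junctions at both sides
    th_j0, th_j1 = np.pi / 2 - span / 2, np.pi / 2 + span / 2
    n1 = max(4, int(np.ceil((th_j0 - th_lo) * r_mid / h)))
    n2 = max(6, int(np.ceil((th_j1 - th_j0) * r_mid / h)))
    n3 = max(4, int(np.ceil((th_hi - th_j1) * r_mid / h)))
    th = np.concatenate([np.linspace(th_lo, th_j0, n1 + 1),
                         np.linspace(th_j0, th_j1, n2 + 1)[1:],
                         np.linspace(th_j1, th_hi, n3 + 1)[1:]])
    return th, (n1, n1 + n2)


def build_cross_section(geom: DissectionGeometry, h: float = 0.3) -> CrossSectionMesh:
    """Mesh the unloaded cross-section with characteristic element size ``h`` (mm).

    Raises :class:`GeometryError` for degenerate inputs (``flap_fraction``
    outside (0, 1), or ``h`` too coarse for two well-shaped element rows
    through the flap).
    """
    if h <= 0:
        raise GeometryError("element size h must be > 0")
    if not geom.intact and h > 2.0 * geom.flap_thickness_mm:
        raise GeometryError(
            "h too coarse to honor two element rows through the flap; "
            f"use h <= {2.0 * geom.flap_thickness_mm:g} mm"
        )

    if geom.intact:
        return _build_intact(geom, h)
    return _build_dissected(geom, h)


def _grid_mesh(theta, ladders, close: bool):
    """Structured mesh from per-column radial ladders (ncol, nrow)."""
    ncol = len(theta) if not close else len(theta) - 1
    nrow = ladders.shape[1]
    ids = np.arange(ncol * nrow).reshape(ncol, nrow)
    cols = np.cos(theta[:ncol, None]) * ladders[:ncol], np.sin(theta[:ncol, None]) * ladders[:ncol]
    nodes = np.stack([cols[0].ravel(), cols[1].ravel()], axis=1)
    return ids, nodes


def _build_intact(geom: DissectionGeometry, h: float) -> CrossSectionMesh:
    theta, _ = _ring_angles(geom, h)
    t = geom.tl_wall_thickness_mm
    nr = max(2, int(np.round(t / h)))
    radii = geom.inner_radius_mm + np.linspace(0, t, nr + 1)
    close = not geom.symmetry
    ncol_nodes = len(theta) - 1 if close else len(theta)
    ladders = np.tile(radii, (ncol_nodes, 1))
    ids, nodes = _grid_mesh(theta, ladders, close)
    elems, layer = [], []
    ncol_el = len(theta) - 1
    for i in range(ncol_el):
        i1 = (i + 1) % ncol_nodes
        for j in range(nr):
            elems.append([ids[i, j], ids[i, j + 1], ids[i1, j + 1], ids[i1, j]])
            layer.append(TL_WALL)
    elems = np.array(elems)
    inner = np.array([[ids[(i + 1) % ncol_nodes, 0], ids[i, 0]] for i in range(ncol_el)])
    outer = np.array([[ids[i, nr], ids[(i + 1) % ncol_nodes, nr]] for i in range(ncol_el)])
    sym = np.empty((0, 2), dtype=int)
    if geom.symmetry:
        sym = np.array(
            [[ids[0, j], ids[0, j + 1]] for j in range(nr)]
            + [[ids[-1, j], ids[-1, j + 1]] for j in range(nr)]
        )
    sets = dict(
        tl_lumen_surface=inner, flap_tl_side=np.empty((0, 2), int),
        flap_fl_side=np.empty((0, 2), int), fl_wall_inner=np.empty((0, 2), int),
        outer_surface=outer, symmetry_plane=sym,
    )
    mesh = CrossSectionMesh(nodes, elems, np.array(layer), sets, h, geom)
    mesh.validate()
    return mesh


def _build_dissected(geom: DissectionGeometry, h: float) -> CrossSectionMesh:
    if not geom.symmetry:
        raise GeometryError("full-model dissected meshing is not implemented; "
                            "use symmetry=True (half model)")
    theta, j_idx = _ring_angles(geom, h)
    ncol = len(theta)
    R = geom.inner_radius_mm
    tf, tfl, ttl = (geom.flap_thickness_mm, geom.fl_wall_thickness_mm,
                    geom.tl_wall_thickness_mm)
    g0 = geom.initial_gap_mm
    nri = max(2, int(np.round(tf / h)))
    nro = max(2, int(np.round(max(tfl, ttl - tf) / h)))
    if ttl <= tf:
        raise GeometryError("tl_wall_thickness_mm must exceed flap_thickness_mm")

    # blend outer-ladder base/thickness over ~2 columns past the junction
    th_j = theta[j_idx]
    dth = theta[min(j_idx + 2, ncol - 1)] - th_j
    base_i, tout_i = R + tf, ttl - tf
    base_d, tout_d = R + tf + g0, tfl

    inner_ids = np.arange(ncol * (nri + 1)).reshape(ncol, nri + 1)
    inner_r = R + np.linspace(0, tf, nri + 1)
    nodes = []
    for i in range(ncol):
        c, s = np.cos(theta[i]), np.sin(theta[i])
        nodes.extend([(r * c, r * s) for r in inner_r])

    # outer ladder: columns from junction (shared there with inner top) to pi/2
    outer_ids = np.full((ncol, nro + 1), -1, dtype=int)
    nid = ncol * (nri + 1)
    for i in range(ncol):
        c, s = np.cos(theta[i]), np.sin(theta[i])
        if theta[i] <= th_j + 1e-12:  # intact sector: share bottom node row
            w = 0.0
        else:
            w = min(1.0, (theta[i] - th_j) / dth) if dth > 0 else 1.0
        base = (1 - w) * base_i + w * base_d
        tout = (1 - w) * tout_i + w * tout_d
        rr = base + np.linspace(0, tout, nro + 1)
        dissected_col = theta[i] > th_j + 1e-12
        for j, r in enumerate(rr):
            if j == 0 and not dissected_col and abs(base - (R + tf)) < 1e-12:
                outer_ids[i, 0] = inner_ids[i, nri]  # shared interface node
            else:
                outer_ids[i, j] = nid
                nodes.append((r * c, r * s))
                nid += 1
    nodes = np.array(nodes)

    elems, layer = [], []
    for i in range(ncol - 1):
        dissected = 0.5 * (theta[i] + theta[i + 1]) > th_j
        for j in range(nri):
            elems.append([inner_ids[i, j], inner_ids[i, j + 1],
                          inner_ids[i + 1, j + 1], inner_ids[i + 1, j]])
            layer.append(FLAP if dissected else TL_WALL)
        for j in range(nro):
            elems.append([outer_ids[i, j], outer_ids[i, j + 1],
                          outer_ids[i + 1, j + 1], outer_ids[i + 1, j]])
            layer.append(FL_WALL if dissected else TL_WALL)
    elems = np.array(elems)
    layer = np.array(layer)

    def col_edges(ids_row, i_lo, i_hi, inward: bool):
        e = []
        for i in range(i_lo, i_hi):
            a, b = ids_row[i], ids_row[i + 1]
            e.append([b, a] if inward else [a, b])
        return np.array(e, dtype=int) if e else np.empty((0, 2), int)

    # boundary sets (solid on the left of each a->b edge)
    tl_lumen = col_edges(inner_ids[:, 0], 0, j_idx, inward=True)
    flap_tl = col_edges(inner_ids[:, 0], j_idx, ncol - 1, inward=True)
    flap_fl = col_edges(inner_ids[:, nri], j_idx, ncol - 1, inward=False)
    fl_inner = col_edges(outer_ids[:, 0], j_idx, ncol - 1, inward=True)
    outer = col_edges(outer_ids[:, nro], 0, ncol - 1, inward=False)
    sym_edges = (
        [[inner_ids[0, j], inner_ids[0, j + 1]] for j in range(nri)]
        + [[outer_ids[0, j], outer_ids[0, j + 1]] for j in range(nro)]
        + [[inner_ids[-1, j], inner_ids[-1, j + 1]] for j in range(nri)]
        + [[outer_ids[-1, j], outer_ids[-1, j + 1]] for j in range(nro)]
    )
    sets = dict(
        tl_lumen_surface=tl_lumen, flap_tl_side=flap_tl, flap_fl_side=flap_fl,
        fl_wall_inner=fl_inner, outer_surface=outer,
        symmetry_plane=np.array(sym_edges, dtype=int),
    )
    mesh = CrossSectionMesh(nodes, elems, layer, sets, h, geom)
    # snap symmetry columns exactly onto x = 0
    ids = np.unique(mesh.boundary_sets["symmetry_plane"])
    mesh.nodes[ids, 0] = 0.0
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# rigid expansion member
# ---------------------------------------------------------------------------

@dataclass
class ExpansionMember:
    """Rigid circular expansion member (balloon/stent analog).

    The radius is the single kinematic degree of freedom; ``n_segments``
    controls the polygon used for export and resolution guards (contact uses
    the exact circle).
    """

    center: tuple = (0.0, 0.0)
    radius: float = 1.0
    n_segments: int = 64

    def __post_init__(self):
        if self.n_segments < 8:
            raise GeometryError("expansion member needs n_segments >= 8")
        if self.radius <= 0:
            raise GeometryError("member radius must be > 0")

    def polygon(self) -> np.ndarray:
        th = np.linspace(0, 2 * np.pi, self.n_segments, endpoint=False)
        c = np.asarray(self.center, float)
        return c + self.radius * np.stack([np.cos(th), np.sin(th)], axis=1)

    def with_radius(self, r: float) -> "ExpansionMember":
        return replace(self, radius=r)


def make_expansion_member(center=(0.0, 0.0), initial_radius: float = 1.0,
                          n_segments: int = 64) -> ExpansionMember:
    return ExpansionMember(center=center, radius=initial_radius, n_segments=n_segments)


def circle_arc_first_contact(center, arc_radius: float, theta_range=( -np.pi, np.pi),
                             arc_center=(0.0, 0.0)) -> float:
    """Closed-form member radius at first contact with a circular arc.

    Minimum distance from ``center`` to the arc of radius ``arc_radius``
    about ``arc_center`` spanning ``theta_range``.
    """
    c = np.asarray(center, float) - np.asarray(arc_center, float)
    d = float(np.hypot(*c))
    th_c = float(np.arctan2(c[1], c[0])) if d > 0 else 0.5 * sum(theta_range)
    lo, hi = theta_range
    th = min(max(th_c, lo), hi)
    p = arc_radius * np.array([np.cos(th), np.sin(th)])
    return float(np.hypot(*(p - c)))


def first_contact_radius(mesh: CrossSectionMesh, member: ExpansionMember) -> float:
    """Member radius at first touch of the (undeformed) TL luminal surface."""
    ids = np.unique(np.concatenate([
        mesh.boundary_sets["tl_lumen_surface"].ravel(),
        mesh.boundary_sets["flap_tl_side"].ravel(),
    ]).astype(int)) if len(mesh.boundary_sets["flap_tl_side"]) else np.unique(
        mesh.boundary_sets["tl_lumen_surface"].ravel())
    d = np.hypot(*(mesh.nodes[ids] - np.asarray(member.center)).T)
    return float(d.min())


# ---------------------------------------------------------------------------
# minimal legacy-VTK export (inspection only)
# ---------------------------------------------------------------------------

def write_vtk(mesh: CrossSectionMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None, displacement: np.ndarray | None = None):
    """Write the mesh (optionally deformed) as an ASCII legacy VTK file."""
    xy = mesh.nodes + (displacement if displacement is not None else 0.0)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nreappose cross-section\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} float\n")
        for x, y in xy:
            f.write(f"{x:.8g} {y:.8g} 0\n")
        f.write(f"CELLS {mesh.n_elems} {5 * mesh.n_elems}\n")
        for e in mesh.elems:
            f.write("4 " + " ".join(map(str, e)) + "\n")
        f.write(f"CELL_TYPES {mesh.n_elems}\n")
        f.write("9\n" * mesh.n_elems)
        f.write(f"CELL_DATA {mesh.n_elems}\nSCALARS layer int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(map(str, mesh.layer.tolist())) + "\n")
        for name, vals in (cell_data or {}).items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{v:.8g}" for v in np.asarray(vals).ravel()) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals)
                if vals.ndim == 2:
                    f.write(f"VECTORS {name} float\n")
                    for v in vals:
                        f.write(f"{v[0]:.8g} {v[1]:.8g} 0\n")
                else:
                    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(f"{v:.8g}" for v in vals) + "\n")
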