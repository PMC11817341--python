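"""Computational domains for drying simulations and their tetrahedral meshes.

The irregular shrimp-like body is a swept-ellipse solid: elliptical cross
sections carried along a curved planar spine with a taper profile toward
the tail, calibrated so the realized volume matches the measured sample
volume (3.92 cm3 by default).  A finite circular cylinder (the common
literature simplification) and a rectangular slab (for verification against
series solutions) are also provided.

Meshing is deterministic.  Swept solids get a triangulated-disk cross
section extruded along the spine into triangular prisms, each split into
three tetrahedra by a face-local diagonal rule (hence conforming); the
resolution is refined until no element edge exceeds the requested
maximum size.  Slab verification meshes use a structured hexahedral grid
split into five tetrahedra per cell.  Note that enforcing a strict edge
bound on an extruded topology yields roughly twice as many (smaller)
elements as a quality-driven unstructured mesher targeting the same
nominal size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

__all__ = [
    "ShrimpGeometrySpec",
    "CylinderGeometrySpec",
    "SweptEllipseSolid",
    "Mesh",
    "build_shrimp_geometry",
    "build_cylinder_geometry",
    "build_slab_mesh",
    "generate_mesh",
    "mesh_independence_study",
]


@dataclass(frozen=True)
class ShrimpGeometrySpec:
    """Parametric surrogate for the irregular shrimp shape.

    total_length is the spine arc length (m).  first_segment_semi_axes are
    the (in-bending-plane, width) semi-axes (m) of the thickest elliptical
    cross-section; the width semi-axis defaults to half the measured
    11.02 mm first-segment diameter.  taper_profile lists
    (axial fraction, multiplier_a, multiplier_b) control points
    interpolated monotonically along the spine.  spine_control_points are
    quadratic Bezier control points in units of the nominal length.
    When calibrate_volume is set the semi-axes are scaled jointly so the
    realized volume equals target_volume.
    """

    total_length: float = 0.0516
    first_segment_semi_axes: tuple[float, float] = (0.005235, 0.00551)
    taper_profile: tuple[tuple[float, float, float], ...] = (
        (0.00, 0.88, 0.88),
        (0.15, 1.00, 1.00),
        (0.45, 0.97, 0.97),
        (0.70, 0.85, 0.85),
        (0.88, 0.60, 0.60),
        (1.00, 0.32, 0.32),
    )
    spine_control_points: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0),
        (0.5, 0.0, 0.12),
        (1.0, 0.0, 0.0),
    )
    target_volume: float = 3.92e-6
    calibrate_volume: bool = True
    #: probe location as arc-length fraction from the head end (between the
    #: first and second abdominal segments), on the spine.
    probe_arc_fraction: float = 0.25


@dataclass(frozen=True)
class CylinderGeometrySpec:
    """Finite right circular cylinder (m)."""

    diameter: float = 0.011
    length: float = 0.042

    @property
    def volume(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2 * self.length

    @property
    def surface_area(self) -> float:
        r = self.diameter / 2.0
        return 2.0 * math.pi * r * self.length + 2.0 * math.pi * r * r


class SweptEllipseSolid:
    """Solid of elliptical cross-sections swept along a planar spine.

    The spine lies in the x-z plane and is arc-length parameterized on
    [0, 1].  Cross sections are orthogonal to the spine; their centroids
    lie on it, so the solid volume is exactly the arc-length integral of
    the section area (the curvature term of the sweep Jacobian integrates
    to zero over each symmetric section).
    """

    _DENSE = 2001

    def __init__(self, spec: ShrimpGeometrySpec):
        self.spec = spec
        cps = np.asarray(spec.spine_control_points, dtype=float)
        if cps.shape != (3, 3):
            raise ValueError("spine_control_points must be 3 quadratic Bezier points")

        # Dense Bezier sampling, then reparameterize by normalized arc length.
        t = np.linspace(0.0, 1.0, self._DENSE)
        b = ((1 - t)[:, None] ** 2 * cps[0] + 2 * (1 - t)[:, None] * t[:, None] * cps[1]
             + t[:, None] ** 2 * cps[2])
        seg = np.linalg.norm(np.diff(b, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0:
            raise ValueError("degenerate spine")
        scale = spec.total_length / s[-1]
        self._spine_xyz = b * scale
        self._s = s * scale  # arc length at dense samples
        self.arc_length = float(self._s[-1])

        # tangent in the x-z plane
        d = np.gradient(self._spine_xyz, self._s, axis=0)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        self._tangent = d
        # curvature magnitude for the self-intersection check
        dT = np.gradient(d, self._s, axis=0)
        self._curvature = np.linalg.norm(dT, axis=1)

        prof = np.asarray(spec.taper_profile, dtype=float)
        if np.any(np.diff(prof[:, 0]) <= 0):
            raise ValueError("taper profile axial fractions must be increasing")
        self._fa = PchipInterpolator(prof[:, 0], prof[:, 1])
        self._fb = PchipInterpolator(prof[:, 0], prof[:, 2])

        a0, b0 = spec.first_segment_semi_axes
        self._scale_axes = 1.0
        if spec.calibrate_volume:
            raw = self._volume_with_axes(a0, b0)
            self._scale_axes = math.sqrt(spec.target_volume / raw)
        self.semi_axis_a0 = a0 * self._scale_axes
        self.semi_axis_b0 = b0 * self._scale_axes

        kappa_amax = float(np.max(self._curvature) * self.max_semi_axis)
        if kappa_amax >= 1.0:
            raise ValueError(
                f"self-intersecting sweep: curvature x max semi-axis = {kappa_amax:.2f} >= 1"
            )

    # -- profile evaluation -------------------------------------------------
    def semi_axes(self, u):
        """Section semi-axes (a, b) in m at arc-length fraction u."""
        u = np.asarray(u, dtype=float)
        return (self.semi_axis_a0 * self._fa(u), self.semi_axis_b0 * self._fb(u))

    @property
    def max_semi_axis(self) -> float:
        u = np.linspace(0, 1, 201)
        a, b = self.semi_axes(u)
        return float(max(np.max(a), np.max(b)))

    def spine(self, u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        s = u * self.arc_length
        out = np.empty((u.size, 3))
        for k in range(3):
            out[:, k] = np.interp(s, self._s, self._spine_xyz[:, k])
        return out

    def _frame(self, u):
        """Tangent and in-plane normal at u (binormal is the +y axis)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        s = u * self.arc_length
        t = np.empty((u.size, 3))
        for k in range(3):
            t[:, k] = np.interp(s, self._s, self._tangent[:, k])
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        # 90 deg rotation of the (x, z) tangent within the bending plane
        n = np.stack([-t[:, 2], np.zeros(u.size), t[:, 0]], axis=1)
        return t, n

    def point(self, u, dx, dy):
        """Map reference coordinates (u in [0,1]; (dx, dy) in the unit
        disk) to a point inside the solid."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        dx = np.asarray(dx, dtype=float)
        dy = np.asarray(dy, dtype=float)
        a, b = self.semi_axes(u)
        c = self.spine(u)
        _, n = self._frame(u)
        y = np.array([0.0, 1.0, 0.0])
        return c + (a * dx)[:, None] * n + (b * dy)[:, None] * y[None, :]

    def _volume_with_axes(self, a0, b0) -> float:
        u = np.linspace(0, 1, 4001)
        area = math.pi * (a0 * self._fa(u)) * (b0 * self._fb(u))
        return float(np.trapezoid(area, u * self.arc_length))

    @property
    def volume(self) -> float:
        """Exact solid volume (m3) by arc-length quadrature."""
        return self._volume_with_axes(self.semi_axis_a0, self.semi_axis_b0)

    def probe_point(self) -> np.ndarray:
        return self.spine(self.spec.probe_arc_fraction)[0]


def build_shrimp_geometry(spec: ShrimpGeometrySpec | None = None) -> SweptEllipseSolid:
    """Irregular shrimp-shaped solid from a geometry spec."""
    return SweptEllipseSolid(spec or ShrimpGeometrySpec())


def build_cylinder_geometry(spec: CylinderGeometrySpec | None = None) -> SweptEllipseSolid:
    """Right circular cylinder as a straight constant-section sweep.

    The probe sits on the axis at mid-length."""
    spec = spec or CylinderGeometrySpec()
    if spec.diameter <= 0 or spec.length <= 0:
        raise ValueError("cylinder dimensions must be positive")
    r = spec.diameter / 2.0
    gspec = ShrimpGeometrySpec(
        total_length=spec.length,
        first_segment_semi_axes=(r, r),
        taper_profile=((0.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
        spine_control_points=((0, 0, 0), (0.5, 0, 0), (1, 0, 0)),
        target_volume=spec.volume,
        calibrate_volume=False,
        probe_arc_fraction=0.5,
    )
    return SweptEllipseSolid(gspec)


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Conforming tetrahedral mesh with oriented boundary triangles.

    active_boundary marks the boundary faces that carry the convective and
    evaporative boundary conditions (all faces by default; verification
    meshes may restrict it).
    """

    nodes: np.ndarray            # (n, 3) m
    tets: np.ndarray             # (m, 4) int, positively oriented
    boundary_tris: np.ndarray    # (b, 3) int, outward oriented
    probe_point: np.ndarray      # (3,) m
    char_size: float             # requested max edge, m
    active_boundary: np.ndarray = None  # (b,) bool

    def __post_init__(self):
        if self.active_boundary is None:
            self.active_boundary = np.ones(len(self.boundary_tris), dtype=bool)

    # -- element geometry ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0
        return v

    @property
    def volume(self) -> float:
        return float(np.sum(self.tet_volumes()))

    def boundary_area_vectors(self) -> np.ndarray:
        """Outward-oriented area vectors of the boundary triangles."""
        p = self.nodes[self.boundary_tris]
        return 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def boundary_areas(self) -> np.ndarray:
        return np.linalg.norm(self.boundary_area_vectors(), axis=1)

    @property
    def surface_area(self) -> float:
        return float(np.sum(self.boundary_areas()))

    def node_boundary_area(self, active_only: bool = True) -> np.ndarray:
        """Lumped boundary area per node (A_f/3 to each face vertex)."""
        tris = self.boundary_tris
        areas = self.boundary_areas()
        if active_only:
            tris, areas = tris[self.active_boundary], areas[self.active_boundary]
        out = np.zeros(self.n_nodes)
        np.add.at(out, tris.ravel(), np.repeat(areas / 3.0, 3))
        return out

    def max_edge_length(self) -> float:
        e = _tet_edges(self.tets)
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return float(np.max(np.linalg.norm(d, axis=1)))

    # -- distinguished nodes ------------------------------------------------
    @property
    def probe_node(self) -> int:
        return int(np.argmin(np.linalg.norm(self.nodes - self.probe_point, axis=1)))

    @property
    def center_node(self) -> int:
        """Node farthest from the surface -- the cold spot / center."""
        bnodes = np.unique(self.boundary_tris)
        tree = cKDTree(self.nodes[bnodes])
        d, _ = tree.query(self.nodes)
        # ties (e.g. along a cylinder axis) break toward the centroid
        near_max = np.flatnonzero(d >= 0.98 * d.max())
        centroid = self.nodes.mean(axis=0)
        dist_c = np.linalg.norm(self.nodes[near_max] - centroid, axis=1)
        return int(near_max[np.argmin(dist_c)])


_EDGE_IDX = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def _tet_edges(tets: np.ndarray) -> np.ndarray:
    return tets[:, _EDGE_IDX].reshape(-1, 2)


# Five-tet decomposition of a hexahedron with vertices numbered by bit
# pattern (x, y, z) -> index x + 2y + 4z.  Parity A has the central tet on
# (1,2,4,7), parity B on (0,3,5,6); alternating the two on a checkerboard
# makes the face diagonals agree between neighboring cells.
_FIVE_TETS_A = np.array(
    [[0, 1, 2, 4], [1, 3, 2, 7], [1, 4, 5, 7], [2, 4, 7, 6], [1, 2, 4, 7]]
)
_FIVE_TETS_B = np.array(
    [[0, 1, 3, 5], [0, 3, 2, 6], [0, 4, 5, 6], [3, 5, 7, 6], [0, 3, 5, 6]]
)


def _structured_tets(nu: int, nc: int):
    """Tets and boundary of an (nu x nc x nc)-cell structured grid with
    checkerboard five-tet splitting.  Returns (tets, node_index_shape)."""
    def nid(l, i, j):
        return (l * (nc + 1) + i) * (nc + 1) + j

    L, I, J = np.meshgrid(np.arange(nu), np.arange(nc), np.arange(nc), indexing="ij")
    L, I, J = L.ravel(), I.ravel(), J.ravel()
    corners = np.stack(
        [
            nid(L, I, J),
            nid(L + 1, I, J),
            nid(L, I + 1, J),
            nid(L + 1, I + 1, J),
            nid(L, I, J + 1),
            nid(L + 1, I, J + 1),
            nid(L, I + 1, J + 1),
            nid(L + 1, I + 1, J + 1),
        ],
        axis=1,
    )  # (cells, 8) with bit order (x=l, y=i, z=j)
    parity = (L + I + J) % 2
    tets = np.where(
        parity[:, None, None] == 0,
        corners[:, _FIVE_TETS_A],
        corners[:, _FIVE_TETS_B],
    ).reshape(-1, 4)
    return tets


def _boundary_faces(tets: np.ndarray):
    """Boundary triangles (outward oriented) of a tet mesh."""
    # local faces opposite each vertex, oriented so the normal points away
    # from the opposite vertex for a positively oriented tet
    fidx = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, fidx].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    same_next = np.all(ks[:-1] == ks[1:], axis=1)
    count = np.ones(len(ks), dtype=int)
    # a face shared by two tets appears exactly twice
    single = np.ones(len(ks), dtype=bool)
    single[:-1] &= ~same_next
    single[1:] &= ~same_next
    return faces[order[single]]


def generate_mesh(solid: SweptEllipseSolid, max_element_size: float,
                  max_refine_iters: int = 12) -> Mesh:
    """Tetrahedral mesh of a swept solid with no edge longer than
    max_element_size (m).

    Cross sections are triangulated on the unit disk (spiderweb pattern)
    and extruded along the spine into triangular prisms, each split into
    three tetrahedra by the smallest-vertex-index diagonal rule (a
    face-local rule, hence conforming).  Axial layer spacing is variable:
    thin tapered sections admit larger axial steps within the diagonal
    budget sqrt(axial^2 + cross^2) <= max size.  Fully deterministic."""
    if max_element_size <= 0:
        raise ValueError("max_element_size must be positive")
    h = float(max_element_size)
    amax = solid.max_semi_axis
    # ring count from the in-section edge bound: the longest section edge
    # scales as e2d(nr) * local max semi-axis
    nr, e2d = 2, float("inf")
    while nr <= 200:
        pts2d, tri = _disk_triangulation(nr)
        e2d = _max_edge_2d(pts2d, tri)
        if e2d * amax <= 0.95 * h:
            break
        nr += 1

    def layer_positions(safety: float) -> np.ndarray:
        us = [0.0]
        while us[-1] < 1.0:
            u0 = us[-1]
            du = 0.0
            for _ in range(3):  # fixed point on the interval's max section
                uu = np.linspace(u0, min(u0 + max(du, 1e-3), 1.0), 5)
                a, b = solid.semi_axes(uu)
                cross = e2d * float(np.maximum(a, b).max())
                s_a = safety * math.sqrt(max(h * h - cross * cross,
                                             (0.15 * h) ** 2))
                du = s_a / solid.arc_length
            us.append(min(u0 + du, 1.0))
        u = np.asarray(us)
        # stretch the last (short) step into the neighbors
        if len(u) > 2 and (u[-1] - u[-2]) < 0.5 * (u[-2] - u[-3]):
            u = np.concatenate([u[:-2], [0.5 * (u[-3] + u[-1]), u[-1]]])
        return u

    me = None
    safety = 0.97
    for _ in range(max_refine_iters):
        mesh, e_intra, e_inter = _mesh_swept(solid, layer_positions(safety), nr)
        me = max(e_intra, e_inter)
        if me <= h * (1 + 1e-12):
            mesh.char_size = h
            return mesh
        if e_intra > h:
            nr += 1
        if e_inter > h:
            safety *= 0.97 * h / e_inter
    raise RuntimeError(
        f"mesh refinement did not satisfy the edge bound {h} m "
        f"(last max edge {me:.4g} m)"
    )


def _max_edge_2d(pts: np.ndarray, tri: np.ndarray) -> float:
    edges = np.unique(np.sort(tri[:, [[0, 1], [1, 2], [0, 2]]]
                              .reshape(-1, 2), axis=1), axis=0)
    return float(np.max(np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]],
                                       axis=1)))


def _disk_points(nr: int) -> np.ndarray:
    """Spiderweb point set on the unit disk: a center node plus rings of
    6k nodes at radius k/nr, aligned at sector boundaries (Delaunay
    tie-breaking on the cocircular patterns is deterministic)."""
    pts = [(0.0, 0.0)]
    for k in range(1, nr + 1):
        m = 6 * k
        ang = 2.0 * math.pi * np.arange(m) / m
        r = k / nr
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.asarray(pts)


def _disk_triangulation(nr: int):
    """Deterministic near-uniform triangulation of the unit disk."""
    from scipy.spatial import Delaunay

    pts = _disk_points(nr)
    tri = Delaunay(pts).simplices.copy()
    # normalize to counter-clockwise orientation
    p = pts[tri]
    det = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
           - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = det < 0
    tri[flip, 1], tri[flip, 2] = tri[flip, 2].copy(), tri[flip, 1].copy()
    return pts, tri


# Prism-to-tet decomposition (3 tets per prism).  Each prism is first
# rotated/flipped so its smallest global vertex index sits at local
# position 0; every quad face is then cut by the diagonal through the
# face's smallest global index, which is a face-local rule and therefore
# conforming between neighboring prisms.
_PRISM_NORMALIZE = np.array([
    [0, 1, 2, 3, 4, 5],
    [1, 2, 0, 4, 5, 3],
    [2, 0, 1, 5, 3, 4],
    [3, 5, 4, 0, 2, 1],
    [4, 3, 5, 1, 0, 2],
    [5, 4, 3, 2, 1, 0],
])
_PRISM_TETS_A = np.array([[0, 1, 2, 5], [0, 1, 5, 4], [0, 4, 5, 3]])
_PRISM_TETS_B = np.array([[0, 1, 2, 4], [0, 4, 2, 5], [0, 4, 5, 3]])


def _split_prisms(tri: np.ndarray, n_layers: int, npts: int) -> np.ndarray:
    """Tetrahedra of an extruded triangulation: layer l holds nodes
    [l*npts, (l+1)*npts)."""
    base = (np.arange(n_layers) * npts)[:, None, None]
    bot = tri[None, :, :] + base            # (L, nt, 3)
    top = bot + npts
    prisms = np.concatenate([bot, top], axis=2).reshape(-1, 6)
    pos = np.argmin(prisms, axis=1)
    norm = np.take_along_axis(prisms, _PRISM_NORMALIZE[pos], axis=1)
    cond = (np.minimum(norm[:, 1], norm[:, 5])
            < np.minimum(norm[:, 2], norm[:, 4]))
    tets_a = norm[:, _PRISM_TETS_A]         # (P, 3, 4)
    tets_b = norm[:, _PRISM_TETS_B]
    return np.where(cond[:, None, None], tets_a, tets_b).reshape(-1, 4)


def _mesh_swept(solid: SweptEllipseSolid, u: np.ndarray, nr: int):
    pts2d, tri = _disk_triangulation(nr)
    npts = len(pts2d)
    nu = len(u) - 1
    nodes = np.empty(((nu + 1) * npts, 3))
    for l, ul in enumerate(u):
        uu = np.full(npts, ul)
        nodes[l * npts:(l + 1) * npts] = solid.point(uu, pts2d[:, 0],
                                                     pts2d[:, 1])

    tets = _split_prisms(tri, nu, npts)
    # enforce positive orientation
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    tris = _boundary_faces(tets)
    mesh = Mesh(
        nodes=nodes,
        tets=tets,
        boundary_tris=tris,
        probe_point=solid.probe_point(),
        char_size=float("nan"),
    )
    if np.any(mesh.tet_volumes() <= 0):
        raise RuntimeError("mesh generation produced degenerate tetrahedra")
    edges = _tet_edges(tets)
    lengths = np.linalg.norm(nodes[edges[:, 0]] - nodes[edges[:, 1]], axis=1)
    intra = (edges[:, 0] // npts) == (edges[:, 1] // npts)
    e_intra = float(lengths[intra].max())
    e_inter = float(lengths[~intra].max())
    return mesh, e_intra, e_inter


def build_slab_mesh(thickness: float, width: float, depth: float,
                    n_thickness: int, n_lateral: int = 2,
                    flux_axis: int = 0) -> Mesh:
    """Rectangular slab mesh whose active boundary is restricted to the
    two faces normal to flux_axis.

    Used for verification against the one-dimensional series solution:
    the inactive lateral faces carry no flux, making the problem
    effectively 1-D through the thickness.
    """
    dims = [thickness, width, depth]
    divs = [n_thickness, n_lateral, n_lateral]
    # reuse the structured generator on a box: axial = axis 0 here
    nu, nc = divs[0], max(divs[1], divs[2])
    gx = np.linspace(0, dims[0], nu + 1)
    gy = np.linspace(0, dims[1], nc + 1)
    gz = np.linspace(0, dims[2], nc + 1)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tets = _structured_tets(nu, nc)
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    tris = _boundary_faces(tets)
    centers = nodes[tris].mean(axis=1)
    ax = flux_axis
    active = (np.isclose(centers[:, ax], 0.0, atol=1e-12 + 1e-9 * dims[ax])
              | np.isclose(centers[:, ax], dims[ax], atol=1e-12 + 1e-9 * dims[ax]))
    probe = np.array([dims[0] / 2, dims[1] / 2, dims[2] / 2])
    return Mesh(nodes=nodes, tets=tets, boundary_tris=tris,
                probe_point=probe, char_size=thickness / n_thickness,
                active_boundary=active)


def mesh_independence_study(solid: SweptEllipseSolid, cfg,
                            sizes: Sequence[float],
                            rel_tol: float = 0.01) -> pd.DataFrame:
    """Convergence of the center moisture at the end of the run as the
    mesh is refined.

    Returns a table of (size_m, n_elements, Xdb_center_final, converged);
    converged flags rows whose center moisture differs from the previous
    (coarser) row by less than rel_tol.  Sizes must be descending.
    """
    from .solver import simulate  # local import: solver depends on geometry

    sizes = list(sizes)
    if any(b > a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("mesh sizes must be descending")
    rows = []
    prev = None
    for size in sizes:
        mesh = generate_mesh(solid, size)
        res = simulate(mesh, cfg)
        xc = float(res.curve.Xdb_center[-1])
        conv = prev is not None and abs(xc - prev) <= rel_tol * abs(prev)
        rows.append({"size_m": size, "n_elements": mesh.n_elements,
                     "Xdb_center_final": xc, "converged": bool(conv)})
        prev = xc
    return pd.DataFrame(rows)
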