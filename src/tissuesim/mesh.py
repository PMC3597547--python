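"""Simplex and polygonal (vertex) meshes, neighbour queries, mesh fixtures.

Simplex meshes (triangles in 2D, tetrahedra in 3D) back the finite-element
solves and the mesh-based cell-centre populations; polygonal vertex meshes
back the vertex-dynamics paradigm.  Delaunay construction and neighbour
searches delegate to scipy.spatial; polygon geometry and its analytic shape
gradients (needed by the vertex free energy) are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "Node", "SimplexMesh", "VertexMesh", "MeshError",
    "delaunay_triangulate", "neighbour_pairs_mesh", "neighbour_pairs_radius",
    "polygon_measures", "shape_gradients", "read_triangle_mesh",
    "disc_mesh", "honeycomb_vertex_mesh", "regular_grid",
    "crypt_villus_points", "CryptVillusSurface",
]


class MeshError(ValueError):
    pass


@dataclass
class Node:
    id: int
    coords: np.ndarray
    is_boundary: bool = False


class SimplexMesh:
    """Linear simplex mesh: triangles (2D) or tetrahedra (3D).

    Element node orderings are normalized so every signed area/volume is
    strictly positive.  Boundary faces are faces bordering exactly one
    element; nodes on such faces carry ``is_boundary``.
    """

    def __init__(self, points: np.ndarray, elements: np.ndarray):
        points = np.asarray(points, dtype=float)
        elements = np.asarray(elements, dtype=int)
        if points.ndim != 2 or points.shape[1] not in (2, 3):
            raise MeshError("points must be (N,2) or (N,3)")
        if not np.all(np.isfinite(points)):
            raise MeshError("non-finite node coordinates")
        dim = points.shape[1]
        if elements.ndim != 2 or elements.shape[1] != dim + 1:
            raise MeshError(f"elements must have {dim + 1} nodes in {dim}D")
        if elements.min(initial=0) < 0 or elements.max(initial=-1) >= len(points):
            raise MeshError("element references node id out of range")
        self.points = points
        self.dim = dim
        self.elements = self._orient_positive(points, elements)
        self._boundary_faces = None
        self._boundary_node_ids = None
        self._nodes = None

    # boundary structure is computed lazily: neighbour queries on frequently
    # rebuilt Delaunay meshes never touch it

    @property
    def boundary_faces(self):
        if self._boundary_faces is None:
            self._boundary_faces = self._find_boundary_faces(self.elements)
        return self._boundary_faces

    @property
    def boundary_node_ids(self) -> np.ndarray:
        if self._boundary_node_ids is None:
            bnodes = set()
            for f in self.boundary_faces:
                bnodes.update(f)
            self._boundary_node_ids = np.array(sorted(bnodes), dtype=int)
        return self._boundary_node_ids

    @property
    def nodes(self):
        if self._nodes is None:
            bset = set(self.boundary_node_ids.tolist())
            self._nodes = [Node(i, self.points[i], i in bset)
                           for i in range(len(self.points))]
        return self._nodes

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _orient_positive(points, elements):
        els = elements.copy()
        v = points[els[:, 1:]] - points[els[:, :1]]
        vol = np.linalg.det(v)
        if np.any(vol == 0):
            k = int(np.nonzero(vol == 0)[0][0])
            raise MeshError(f"element {k} is degenerate (zero measure)")
        neg = vol < 0
        els[neg, -2], els[neg, -1] = els[neg, -1].copy(), els[neg, -2].copy()
        return els

    @staticmethod
    def _find_boundary_faces(elements):
        from collections import Counter
        nv = elements.shape[1]
        faces = Counter()
        for el in elements:
            for drop in range(nv):
                face = tuple(sorted(np.delete(el, drop)))
                faces[face] += 1
        return [list(f) for f, c in sorted(faces.items()) if c == 1]

    # -- queries ---------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_measure(self, k: int) -> float:
        el = self.elements[k]
        v = self.points[el[1:]] - self.points[el[0]]
        from math import factorial
        return np.linalg.det(v) / factorial(self.dim)

    def element_centroid(self, k: int) -> np.ndarray:
        return self.points[self.elements[k]].mean(axis=0)

    def centroids(self) -> np.ndarray:
        return self.points[self.elements].mean(axis=1)

    def check_invariants(self) -> None:
        for k in range(self.n_elements):
            if self.element_measure(k) <= 0:
                raise MeshError(f"element {k} has non-positive measure")


class VertexMesh:
    """2D polygonal tiling: shared vertices, one CCW polygon per cell."""

    def __init__(self, vertices: np.ndarray, cell_polygons: list[list[int]]):
        self.vertices = np.asarray(vertices, dtype=float)
        polys = []
        for poly in cell_polygons:
            poly = list(poly)
            if len(poly) < 3:
                raise MeshError("polygon with fewer than 3 vertices")
            a, _, _ = polygon_measures(self.vertices[poly])
            polys.append(poly if a > 0 else poly[::-1])  # normalize to CCW
        self.cell_polygons = polys

    @property
    def n_cells(self) -> int:
        return len(self.cell_polygons)

    def polygon_points(self, c: int) -> np.ndarray:
        return self.vertices[self.cell_polygons[c]]

    def edges(self) -> dict:
        """Map undirected vertex-id edge -> list of adjacent cell indices."""
        out: dict[tuple, list] = {}
        for c, poly in enumerate(self.cell_polygons):
            n = len(poly)
            for i in range(n):
                e = tuple(sorted((poly[i], poly[(i + 1) % n])))
                out.setdefault(e, []).append(c)
        return out

    def check_invariants(self) -> None:
        for c, poly in enumerate(self.cell_polygons):
            a, _, _ = polygon_measures(self.vertices[poly])
            if a <= 0:
                raise MeshError(f"polygon {c} has non-positive area")
        for e, cells in self.edges().items():
            if len(cells) > 2:
                raise MeshError(f"edge {e} shared by >2 polygons")


# ---------------------------------------------------------------------------
# Delaunay & neighbour queries
# ---------------------------------------------------------------------------

def delaunay_triangulate(points) -> SimplexMesh:
    """Delaunay triangulation of 2D/3D points as a :class:`SimplexMesh`.

    Cocircular/cospherical ties are broken by the underlying (QHull)
    deterministic rule; the empty-circumsphere property always holds.
    Degenerate input (collinear / coplanar) raises :class:`MeshError`.
    """
    pts = np.asarray(points, dtype=float)
    dim = pts.shape[1]
    if len(pts) < dim + 1:
        raise MeshError(f"need at least {dim + 1} points in {dim}D")
    # affine-independence check
    rel = pts - pts[0]
    if np.linalg.matrix_rank(rel, tol=1e-12) < dim:
        kind = "collinear" if dim == 2 else "coplanar"
        raise MeshError(f"degenerate input: points are {kind}")
    tri = Delaunay(pts)
    # QHull can emit sliver simplices of zero measure on ties; drop them
    els = tri.simplices
    v = pts[els[:, 1:]] - pts[els[:, :1]]
    vol = np.abs(np.linalg.det(v))
    return SimplexMesh(pts, els[vol > 1e-12])


def neighbour_pairs_mesh(mesh: SimplexMesh) -> set:
    """Unordered node-id pairs co-occurring in at least one element."""
    els = mesh.elements
    nv = els.shape[1]
    blocks = [els[:, (i, j)] for i in range(nv) for j in range(i + 1, nv)]
    pairs = np.vstack(blocks)
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    return {(int(a), int(b)) for a, b in pairs}


def neighbour_pairs_radius(points, r: float) -> set:
    """Unordered index pairs within Euclidean distance <= r (inclusive)."""
    if r <= 0:
        raise ValueError("interaction radius must be positive")
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(pts)
    return {tuple(sorted(map(int, p))) for p in tree.query_pairs(r)}


# ---------------------------------------------------------------------------
# Polygon geometry
# ---------------------------------------------------------------------------

def polygon_measures(polygon) -> tuple[float, float, np.ndarray]:
    """(signed shoelace area, perimeter, centroid) of an ordered 2D polygon.

    Area is positive for counter-clockwise orientation; the centroid is the
    area centroid (of the absolute region).
    """
    p = np.asarray(polygon, dtype=float)
    if len(p) < 3:
        raise MeshError("polygon needs at least 3 vertices")
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    perimeter = float(np.sqrt((xn - x) ** 2 + (yn - y) ** 2).sum())
    if abs(area) < 1e-300:
        centroid = p.mean(axis=0)
    else:
        cx = ((x + xn) * cross).sum() / (6 * area)
        cy = ((y + yn) * cross).sum() / (6 * area)
        centroid = np.array([cx, cy])
    return float(area), perimeter, centroid


def shape_gradients(polygon, vertex_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (d area / d vertex, d perimeter / d vertex) for one vertex.

    Area gradient follows from the shoelace formula:
    dA/dv_i = 0.5 * (v_{i+1} - v_{i-1}) rotated by -90 degrees.
    Perimeter gradient is the sum of the two unit edge vectors pointing
    away from the neighbours.
    """
    p = np.asarray(polygon, dtype=float)
    n = len(p)
    i = vertex_index % n
    prev_, next_ = p[(i - 1) % n], p[(i + 1) % n]
    d = next_ - prev_
    dA = 0.5 * np.array([d[1], -d[0]])
    e_prev = p[i] - prev_
    e_next = p[i] - next_
    dP = np.zeros(2)
    lp, ln = np.linalg.norm(e_prev), np.linalg.norm(e_next)
    if lp > 0:
        dP += e_prev / lp
    if ln > 0:
        dP += e_next / ln
    return dA, dP


# ---------------------------------------------------------------------------
# Triangle / TetGen readers
# ---------------------------------------------------------------------------

def _data_lines(path):
    """Yield (line_number, tokens) skipping blanks and '#' comments."""
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            s = raw.split("#", 1)[0].strip()
            if s:
                yield ln, s.split()


def read_triangle_mesh(node_path, ele_path) -> SimplexMesh:
    """Read a Triangle/TetGen `.node` + `.ele` plain-text pair.

    The index base (0 or 1) is auto-detected from the first node id, per the
    Triangle convention that both bases are legal.  Indices are normalized
    to 0-based internally.
    """
    lines = _data_lines(node_path)
    try:
        ln0, head = next(lines)
    except StopIteration:
        raise MeshError(f"{node_path}: empty file") from None
    try:
        n_nodes, dim = int(head[0]), int(head[1])
    except (ValueError, IndexError):
        raise MeshError(f"{node_path}:{ln0}: bad .node header") from None
    if dim not in (2, 3):
        raise MeshError(f"{node_path}:{ln0}: dimension must be 2 or 3")

    ids, coords = [], []
    for ln, tok in lines:
        if len(tok) < 1 + dim:
            raise MeshError(f"{node_path}:{ln}: expected id + {dim} coords")
        ids.append(int(tok[0]))
        coords.append([float(v) for v in tok[1:1 + dim]])
    if len(ids) != n_nodes:
        raise MeshError(
            f"{node_path}: header declares {n_nodes} nodes, found {len(ids)}")
    base = ids[0]
    if base not in (0, 1):
        raise MeshError(f"{node_path}: first node id must be 0 or 1, got {base}")
    if ids != list(range(base, base + n_nodes)):
        raise MeshError(f"{node_path}: node ids not consecutive from {base}")
    points = np.array(coords)

    lines = _data_lines(ele_path)
    try:
        ln0, head = next(lines)
    except StopIteration:
        raise MeshError(f"{ele_path}: empty file") from None
    n_el, nodes_per = int(head[0]), int(head[1])
    if nodes_per != dim + 1:
        raise MeshError(
            f"{ele_path}:{ln0}: {nodes_per} nodes/element inconsistent with "
            f"{dim}D nodes (expected {dim + 1})")
    elements = []
    for ln, tok in lines:
        if len(tok) < 1 + nodes_per:
            raise MeshError(f"{ele_path}:{ln}: expected id + {nodes_per} node ids")
        el = [int(v) - base for v in tok[1:1 + nodes_per]]
        for v in el:
            if not 0 <= v < n_nodes:
                raise MeshError(
                    f"{ele_path}:{ln}: element {tok[0]} references node "
                    f"{v + base} outside the {n_nodes}-node file")
        elements.append(el)
    if len(elements) != n_el:
        raise MeshError(
            f"{ele_path}: header declares {n_el} elements, found {len(elements)}")
    return SimplexMesh(points, np.array(elements))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def disc_mesh(radius: float, target_edge_length: float) -> SimplexMesh:
    """Good-quality triangulation of a disc from concentric point rings.

    Boundary nodes lie on the circle to ~1e-9 * radius.  Rings are offset
    half a spacing alternately, which keeps triangles close to equilateral
    (useful for discrete-maximum-principle behaviour).
    """
    if radius <= 0 or target_edge_length <= 0:
        raise ValueError("radius and edge length must be positive")
    n_rings = max(1, int(round(radius / target_edge_length)))
    dr = radius / n_rings
    pts = [np.zeros(2)]
    for k in range(1, n_rings + 1):
        r = k * dr
        n_theta = max(6, int(round(2 * np.pi * r / dr)))
        offset = 0.5 * (k % 2) * 2 * np.pi / n_theta
        th = offset + 2 * np.pi * np.arange(n_theta) / n_theta
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    points = np.vstack(pts)
    mesh = delaunay_triangulate(points)
    # snap outermost ring exactly onto the circle
    rr = np.linalg.norm(mesh.points, axis=1)
    on_rim = rr > radius - 0.5 * dr
    mesh.points[on_rim] *= (radius / rr[on_rim])[:, None]
    return SimplexMesh(mesh.points, mesh.elements)


def regular_grid(nx: int, ny: int, dx: float) -> SimplexMesh:
    """nx*ny nodes on a square lattice split into 2*(nx-1)*(ny-1) triangles."""
    if nx < 2 or ny < 2 or dx <= 0:
        raise ValueError("grid needs nx, ny >= 2 and dx > 0")
    xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dx, indexing="ij")
    points = np.column_stack([xs.ravel(), ys.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    els = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            els.append([a, b, c])
            els.append([a, c, d])
    return SimplexMesh(points, np.array(els))


def honeycomb_vertex_mesh(nx: int, ny: int, side: float = None) -> VertexMesh:
    """nx*ny regular hexagons (pointy-top) sharing vertices.

    Default side length makes the hexagon area 1 (the conventional unit
    target area of vertex-dynamics monolayers).
    """
    if nx < 1 or ny < 1:
        raise ValueError("need at least one hexagon in each direction")
    if side is None:
        side = float(np.sqrt(2.0 / (3 * np.sqrt(3))))  # area = 1
    s = side
    w = np.sqrt(3) * s           # hexagon width
    vert_lookup: dict[tuple, int] = {}
    vertices: list[np.ndarray] = []

    def vid(p):
        key = (round(p[0] / s, 6), round(p[1] / s, 6))
        if key not in vert_lookup:
            vert_lookup[key] = len(vertices)
            vertices.append(np.asarray(p, dtype=float))
        return vert_lookup[key]

    polys = []
    # pointy-top hexagon corners, CCW starting east-ish
    ang = np.pi / 6 + np.arange(6) * np.pi / 3
    corners = np.column_stack([s * np.cos(ang), s * np.sin(ang)])
    for j in range(ny):
        for i in range(nx):
            cx = i * w + (j % 2) * w / 2
            cy = j * 1.5 * s
            polys.append([vid(corners[k] + (cx, cy)) for k in range(6)])
    return VertexMesh(np.array(vertices), polys)


# ---------------------------------------------------------------------------
# Crypt-villus parametric surface
# ---------------------------------------------------------------------------

class CryptVillusSurface:
    """Flat epithelial sheet (z=0) pierced by test-tube crypts and a villus.

    Each crypt is a cylinder of radius `r` descending from the plane to depth
    `-L` with a hemispherical bottom cap; the villus is the same shape
    ascending to `+L_v`.  Closest-point projection onto the composite surface:
    the candidate patch with the smallest distance wins, and exact medial-axis
    ties are resolved in favour of the tube wall over the plane (axis-priority
    rule), keeping projection deterministic.
    """

    def __init__(self, crypt_centres, crypt_radius: float, crypt_depth: float,
                 villus_centre, villus_radius: float, villus_height: float):
        self.crypt_centres = [np.asarray(c, dtype=float) for c in crypt_centres]
        self.crypt_radius = crypt_radius
        self.crypt_depth = crypt_depth
        self.villus_centre = np.asarray(villus_centre, dtype=float)
        self.villus_radius = villus_radius
        self.villus_height = villus_height

    # -- per-patch closest points -------------------------------------------

    @staticmethod
    def _tube_project(p, centre, radius, extent):
        """Closest point on a tube along z (sign of `extent` gives direction).

        Tube = cylinder wall from z=0 to z=extent plus hemispherical cap at
        the far end, open at z=0.
        """
        sgn = 1.0 if extent > 0 else -1.0
        L = abs(extent)
        cap_c = np.array([centre[0], centre[1], sgn * (L - radius) if L > radius else 0.0])
        # local cylindrical coords
        dxy = p[:2] - centre
        rho = np.linalg.norm(dxy)
        u = dxy / rho if rho > 1e-14 else np.array([1.0, 0.0])
        zc = p[2] * sgn  # height measured into the tube (positive inward)
        wall_top = 0.0
        wall_bot = L - radius  # wall spans z' in [0, L - radius]
        if zc >= wall_top and zc <= wall_bot:
            q = np.array([centre[0] + radius * u[0],
                          centre[1] + radius * u[1], p[2]])
        elif zc > wall_bot:
            # hemispherical cap: project radially from cap centre
            v = p - cap_c
            nv = np.linalg.norm(v)
            if nv < 1e-14:
                v = np.array([0.0, 0.0, sgn])
                nv = 1.0
            q = cap_c + radius * v / nv
        else:
            # outside the mouth: clamp to the rim circle at z=0
            q = np.array([centre[0] + radius * u[0],
                          centre[1] + radius * u[1], 0.0])
        return q

    def _candidates(self, p):
        cands = []
        for c in self.crypt_centres:
            cands.append(self._tube_project(p, c, self.crypt_radius,
                                            -self.crypt_depth))
        cands.append(self._tube_project(p, self.villus_centre,
                                        self.villus_radius, self.villus_height))
        # plane patch: z=0 outside all tube mouths
        q = np.array([p[0], p[1], 0.0])
        # push plane projection out of any tube mouth it falls into
        for c, r in [(c, self.crypt_radius) for c in self.crypt_centres] + \
                    [(self.villus_centre, self.villus_radius)]:
            d = q[:2] - c
            rho = np.linalg.norm(d)
            if rho < r:
                u = d / rho if rho > 1e-14 else np.array([1.0, 0.0])
                q = np.array([c[0] + r * u[0], c[1] + r * u[1], 0.0])
        cands.append(q)
        return cands

    def project(self, p) -> np.ndarray:
        """Closest point on the composite surface (tube beats plane on ties)."""
        p = np.asarray(p, dtype=float)
        cands = self._candidates(p)
        dists = [np.linalg.norm(p - q) for q in cands]
        best = int(np.argmin(dists))          # tubes listed first => priority
        return cands[best]

    def project_points(self, pts) -> np.ndarray:
        return np.array([self.project(p) for p in np.asarray(pts, dtype=float)])

    def crypt_depth_of(self, p) -> tuple[int, float]:
        """(crypt index, depth below the plane) for the nearest crypt; depth 0
        if the point is not below the plane."""
        p = np.asarray(p, dtype=float)
        dists = [np.linalg.norm(p[:2] - c) for c in self.crypt_centres]
        k = int(np.argmin(dists))
        return k, max(0.0, -p[2])

    def in_crypt(self, p, k: int) -> bool:
        p = np.asarray(p, dtype=float)
        return (p[2] < -1e-9 and
                np.linalg.norm(p[:2] - self.crypt_centres[k])
                <= 1.5 * self.crypt_radius)


def crypt_villus_points(n_crypts: int, n_cells: int, stream,
                        surface: CryptVillusSurface | None = None):
    """Random initial cell centres on a crypt-villus surface.

    Returns (points, surface).  Cells are seeded inside the crypts (biased
    toward the base, where the proliferative compartment sits) plus a few on
    the plane between them.
    """
    if n_crypts < 1 or n_cells < n_crypts:
        raise ValueError("need at least one cell per crypt")
    if surface is None:
        ring_r = 3.0
        centres = [ring_r * np.array([np.cos(a), np.sin(a)])
                   for a in 2 * np.pi * np.arange(n_crypts) / n_crypts]
        surface = CryptVillusSurface(centres, crypt_radius=1.0, crypt_depth=3.0,
                                     villus_centre=(0.0, 0.0),
                                     villus_radius=1.0, villus_height=4.0)
    pts = []
    per_crypt = n_cells // n_crypts
    r = surface.crypt_radius
    n_ring = max(3, int(round(2 * np.pi * r)))   # ~unit spacing on the wall
    for k, c in enumerate(surface.crypt_centres):
        n_here = per_crypt + (1 if k < n_cells % n_crypts else 0)
        # regular rings up the crypt wall, jittered to break symmetry
        placed = 0
        ring = 0
        while placed < n_here:
            depth = surface.crypt_depth - 0.3 - 0.9 * ring
            phase = float(stream.uniform(0, 2 * np.pi))
            for i in range(n_ring):
                if placed >= n_here:
                    break
                theta = phase + 2 * np.pi * i / n_ring
                jz = 0.1 * float(stream.uniform(-1, 1))
                p = np.array([c[0] + r * np.cos(theta),
                              c[1] + r * np.sin(theta),
                              -max(0.3, depth + jz)])
                pts.append(surface.project(p))
                placed += 1
            ring += 1
    return np.array(pts), surface
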