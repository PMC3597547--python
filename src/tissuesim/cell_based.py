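"""Cell-based tissue simulation: cells, populations, forces, and the engine.

Five population paradigms are provided:

* ``CaBasedPopulation``      — lattice sites holding one or more cells,
* ``PottsPopulation``        — cells as lattice-site domains with Metropolis
                               dynamics on an interface + area Hamiltonian,
* ``NodeBasedPopulation``    — off-lattice cell centres, neighbours within an
                               interaction radius,
* ``MeshBasedPopulation``    — off-lattice cell centres, neighbours from the
                               Delaunay triangulation of the centres,
* ``VertexBasedPopulation``  — cells as polygons moved by the gradient of a
                               tissue free energy.

Off-lattice motion is overdamped: eta * dr/dt = sum of forces, integrated by
forward Euler.  Lengths are in cell diameters, times in hours.

The :class:`Simulator` runs a fixed per-step event order
(cycle/oxygen/Wnt -> signalling -> deaths -> divisions -> movement ->
PDE re-solve -> output); changing this order changes results, so it is part
of the reproducibility contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .core import RandomStream
from .mesh import (SimplexMesh, VertexMesh, delaunay_triangulate,
                   neighbour_pairs_mesh, neighbour_pairs_radius,
                   polygon_measures, shape_gradients)

__all__ = [
    "Cell", "FixedDuration", "UniformStochastic", "OxygenDependent",
    "SpringParams", "PottsParams", "VertexForceParams",
    "CaBasedPopulation", "PottsPopulation", "NodeBasedPopulation",
    "MeshBasedPopulation", "VertexBasedPopulation",
    "spring_force", "step_positions", "do_divisions",
    "apply_oxygen_rule", "potts_hamiltonian", "potts_mc_sweep",
    "metropolis_accept",
    "vertex_energy", "vertex_force",
    "track_ancestors", "is_monoclonal", "project_to_surface",
    "wnt_proliferation_rule", "sloughing_killer", "ca_migration_step",
    "Simulator", "OxygenCoupling", "run_simulation", "StepSizeError",
]


class StepSizeError(RuntimeError):
    """Per-step displacement exceeded half a cell diameter."""


# ---------------------------------------------------------------------------
# Cells and cycle models
# ---------------------------------------------------------------------------

@dataclass
class FixedDuration:
    duration: float = 12.0            # hours


@dataclass
class UniformStochastic:
    d_min: float = 12.0
    d_max: float = 16.0

    def draw(self, stream: RandomStream) -> float:
        return float(stream.uniform(self.d_min, self.d_max))


@dataclass
class OxygenDependent:
    """Oxygen-gated cycling: arrest below c_quiescent, death below c_death.

    Concentrations are on the scale of the boundary value (1 at the rim).
    The low-oxygen timer accumulates while c <= c_death and resets once
    c > c_death; cells die after tau_death hours of sustained exposure.
    Base division times are drawn uniformly (like UniformStochastic).
    """
    c_quiescent: float = 0.7
    c_death: float = 0.3
    tau_death: float = 2.0            # hours
    d_min: float = 12.0
    d_max: float = 16.0

    def draw(self, stream: RandomStream) -> float:
        return float(stream.uniform(self.d_min, self.d_max))


class Cell:
    """One cell: lineage, cycle progress, per-cell scalar data."""

    def __init__(self, cell_id: int, ancestor_id: int, birth_time: float,
                 cycle_model, duration: float):
        self.id = cell_id
        self.ancestor_id = ancestor_id     # immutable after creation
        self.birth_time = birth_time
        self.cycle_model = cycle_model
        self.duration = duration           # target cycle length, hours
        self.age = 0.0                     # accumulated *cycling* time
        self.alive = True
        self.arrested = False
        self.low_oxygen_timer = 0.0
        self.data: dict[str, float] = {}

    def ready_to_divide(self) -> bool:
        return self.alive and not self.arrested and self.age >= self.duration

    def __repr__(self):
        return f"Cell({self.id}, ancestor={self.ancestor_id}, age={self.age:.2f})"


def _draw_duration(cycle_model, stream: RandomStream) -> float:
    if isinstance(cycle_model, FixedDuration):
        return cycle_model.duration
    return cycle_model.draw(stream)


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass
class SpringParams:
    """Linear spring between neighbouring cell centres.

    Rest length ramps from 0.3*s to s over `ramp_duration` hours after a
    division, following the usual overlapping-spheres convention.
    """
    stiffness: float = 15.0
    rest_length: float = 1.0           # cell diameters
    ramp_duration: float = 1.0         # hours
    cutoff: float = 1.5                # no interaction beyond this distance
    repulsion_only: bool = False

    def effective_rest_length(self, maturity: float) -> float:
        if maturity >= self.ramp_duration:
            return self.rest_length
        frac = max(0.0, maturity) / self.ramp_duration
        return self.rest_length * (0.3 + 0.7 * frac)


@dataclass
class PottsParams:
    """Interface + area Hamiltonian of the cellular Potts model."""
    J: dict = dataclass_field(default_factory=lambda: {
        ("cell", "cell"): 0.1, ("cell", "medium"): 0.2})
    area_stiffness: float = 1.0
    target_area: float = 16.0          # lattice sites
    temperature: float = 0.1
    neighbourhood: str = "von-neumann"

    def j_between(self, type_a: str, type_b: str) -> float:
        key = (type_a, type_b)
        if key in self.J:
            return self.J[key]
        return self.J[(type_b, type_a)]


@dataclass
class VertexForceParams:
    """Area + perimeter elasticity and edge adhesion of the vertex model."""
    area_stiffness: float = 50.0       # K_A
    target_area: float = 1.0           # A0
    perimeter_stiffness: float = 1.0   # K_P
    target_perimeter: float = 0.0      # P0
    gamma_interior: float = 0.0        # adhesion energy per unit edge length
    gamma_boundary: float = 0.0


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

class _PopulationBase:
    def __init__(self):
        self.cells: dict[int, Cell] = {}
        self._next_id = 0

    def new_cell_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def living_cells(self):
        return [c for c in self.cells.values() if c.alive]


class _CentreBased(_PopulationBase):
    """Shared machinery of node-based and mesh-based populations."""

    def __init__(self, positions, cycle_model, stream: RandomStream,
                 birth_time: float = 0.0):
        super().__init__()
        positions = np.asarray(positions, dtype=float)
        self.dim = positions.shape[1]
        self.positions: dict[int, np.ndarray] = {}
        # (parent, daughter) pairs still inside the rest-length ramp
        self.ramp_pairs: dict[tuple, float] = {}     # (a, b) -> division time
        # newborn cells are small: their radius (hence rest length to any
        # neighbour) grows over the ramp duration after their birth
        self.newborn: dict[int, float] = {}          # cell id -> birth time
        for p in positions:
            cid = self.new_cell_id()
            cell = Cell(cid, ancestor_id=cid, birth_time=birth_time,
                        cycle_model=cycle_model,
                        duration=_draw_duration(cycle_model, stream))
            # desynchronize the initial population
            if np.isfinite(cell.duration):
                cell.age = float(stream.uniform(0.0, cell.duration))
            self.cells[cid] = cell
            self.positions[cid] = np.array(p, dtype=float)

    # -- array views -------------------------------------------------------

    def id_array(self) -> list[int]:
        return list(self.positions.keys())

    def position_array(self) -> np.ndarray:
        return np.array(list(self.positions.values()))

    def remove_cell(self, cid: int) -> None:
        self.cells.pop(cid)
        self.positions.pop(cid)
        self.newborn.pop(cid, None)
        for key in [k for k in self.ramp_pairs if cid in k]:
            del self.ramp_pairs[key]

    def add_daughter(self, parent: Cell, pos: np.ndarray, now: float,
                     stream: RandomStream) -> Cell:
        cid = self.new_cell_id()
        daughter = Cell(cid, ancestor_id=parent.ancestor_id, birth_time=now,
                        cycle_model=parent.cycle_model,
                        duration=_draw_duration(parent.cycle_model, stream))
        self.cells[cid] = daughter
        self.positions[cid] = np.array(pos, dtype=float)
        key = (parent.id, cid) if parent.id < cid else (cid, parent.id)
        self.ramp_pairs[key] = now
        self.newborn[cid] = now
        return daughter

    def centroid(self) -> np.ndarray:
        return self.position_array().mean(axis=0)


class NodeBasedPopulation(_CentreBased):
    """Off-lattice centres; neighbours are pairs within `interaction_radius`."""

    def __init__(self, positions, cycle_model, stream, interaction_radius=1.5,
                 birth_time: float = 0.0):
        super().__init__(positions, cycle_model, stream, birth_time)
        self.interaction_radius = interaction_radius

    def neighbour_pairs(self):
        ids = self.id_array()
        pts = self.position_array()
        return [(ids[i], ids[j])
                for i, j in neighbour_pairs_radius(pts, self.interaction_radius)]


class MeshBasedPopulation(_CentreBased):
    """Off-lattice centres; neighbours share a Delaunay element."""

    def __init__(self, positions, cycle_model, stream, birth_time: float = 0.0):
        super().__init__(positions, cycle_model, stream, birth_time)
        self._mesh: SimplexMesh | None = None
        self._mesh_ids: list[int] | None = None

    def invalidate_mesh(self):
        self._mesh = None

    def mesh(self) -> SimplexMesh:
        """Delaunay triangulation of the current centres (cached until moved)."""
        if self._mesh is None:
            self._mesh_ids = self.id_array()
            self._mesh = delaunay_triangulate(self.position_array())
        return self._mesh

    def neighbour_pairs(self):
        mesh = self.mesh()
        ids = self._mesh_ids
        return [(ids[i], ids[j]) for i, j in neighbour_pairs_mesh(mesh)]

    def remove_cell(self, cid):
        super().remove_cell(cid)
        self.invalidate_mesh()

    def add_daughter(self, parent, pos, now, stream):
        d = super().add_daughter(parent, pos, now, stream)
        self.invalidate_mesh()
        return d


class CaBasedPopulation(_PopulationBase):
    """Cellular automaton: each lattice site holds up to `capacity` cells."""

    def __init__(self, shape: tuple, occupied_sites, cycle_model,
                 stream: RandomStream, capacity: int = 1,
                 birth_time: float = 0.0):
        super().__init__()
        if capacity < 1:
            raise ValueError("carrying capacity must be >= 1")
        self.shape = tuple(shape)
        self.dim = len(self.shape)
        self.capacity = capacity
        self.site_of: dict[int, tuple] = {}
        self.occupants: dict[tuple, list[int]] = {}
        for site in occupied_sites:
            site = tuple(site)
            cid = self.new_cell_id()
            cell = Cell(cid, cid, birth_time, cycle_model,
                        _draw_duration(cycle_model, stream))
            if np.isfinite(cell.duration):
                cell.age = float(stream.uniform(0.0, cell.duration))
            self.cells[cid] = cell
            self._place(cid, site)

    def _place(self, cid: int, site: tuple) -> None:
        occ = self.occupants.setdefault(site, [])
        if len(occ) >= self.capacity:
            raise ValueError(f"site {site} already at capacity")
        occ.append(cid)
        self.site_of[cid] = site

    def _unplace(self, cid: int) -> None:
        site = self.site_of.pop(cid)
        self.occupants[site].remove(cid)
        if not self.occupants[site]:
            del self.occupants[site]

    def neighbours_of_site(self, site: tuple):
        out = []
        for axis in range(self.dim):
            for d in (-1, 1):
                nb = list(site)
                nb[axis] += d
                if 0 <= nb[axis] < self.shape[axis]:
                    out.append(tuple(nb))
        return out

    def spare_capacity(self, site: tuple) -> int:
        return self.capacity - len(self.occupants.get(site, []))

    def move_cell(self, cid: int, site: tuple) -> None:
        self._unplace(cid)
        self._place(cid, site)

    def remove_cell(self, cid: int) -> None:
        self._unplace(cid)
        self.cells.pop(cid)


class PottsPopulation(_PopulationBase):
    """Cellular Potts: a 2D spin lattice; spin -1 is medium."""

    MEDIUM = -1

    def __init__(self, spins: np.ndarray, params: PottsParams,
                 cell_types: dict[int, str] | None = None):
        super().__init__()
        self.spins = np.asarray(spins, dtype=int).copy()
        self.params = params
        ids = sorted(int(s) for s in np.unique(self.spins) if s != self.MEDIUM)
        self.cell_types = dict(cell_types or {})
        for cid in ids:
            cell = Cell(cid, cid, 0.0, FixedDuration(np.inf), np.inf)
            self.cells[cid] = cell
            self.cell_types.setdefault(cid, "cell")
        self._next_id = max(ids, default=-1) + 1
        self.areas = Counter(int(s) for s in self.spins.ravel()
                             if s != self.MEDIUM)

    def type_of(self, spin: int) -> str:
        return "medium" if spin == self.MEDIUM else self.cell_types[spin]

    def neighbour_offsets(self):
        if self.params.neighbourhood == "moore":
            return [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0)]
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]


class VertexBasedPopulation(_PopulationBase):
    """Vertex dynamics: one CCW polygon per cell on a shared vertex set."""

    def __init__(self, mesh: VertexMesh, cycle_model=None,
                 stream: RandomStream | None = None,
                 params: VertexForceParams | None = None):
        super().__init__()
        self.mesh = mesh
        self.params = params or VertexForceParams()
        cycle_model = cycle_model or FixedDuration(np.inf)
        self.polygon_of: dict[int, int] = {}
        for k in range(mesh.n_cells):
            cid = self.new_cell_id()
            dur = (_draw_duration(cycle_model, stream) if stream is not None
                   else getattr(cycle_model, "duration", np.inf))
            self.cells[cid] = Cell(cid, cid, 0.0, cycle_model, dur)
            self.polygon_of[cid] = k

    def polygon_points(self, cid: int) -> np.ndarray:
        return self.mesh.polygon_points(self.polygon_of[cid])


# ---------------------------------------------------------------------------
# Forces (centre-based)
# ---------------------------------------------------------------------------

def spring_force(pos_a, pos_b, params: SpringParams, maturity: float = np.inf,
                 stream: RandomStream | None = None) -> np.ndarray:
    """Linear-spring force exerted on the cell at `pos_a` by `pos_b`.

    Magnitude mu * (|r| - s_eff) along the separation axis; attraction beyond
    the rest length unless `repulsion_only`; zero beyond the cutoff.
    Coincident centres are pushed apart along a random unit direction with
    magnitude mu * s (a documented degenerate-case rule; needs `stream`).
    """
    a = np.asarray(pos_a, dtype=float)
    b = np.asarray(pos_b, dtype=float)
    r = b - a
    dist = float(np.linalg.norm(r))
    s_eff = params.effective_rest_length(maturity)
    if dist < 1e-12:
        if stream is None:
            raise ValueError("coincident cell centres with no random stream")
        u = stream.unit_vector(len(a))
        return params.stiffness * params.rest_length * u
    if dist > params.cutoff:
        return np.zeros_like(a)
    overlap = dist - s_eff
    if params.repulsion_only and overlap > 0:
        return np.zeros_like(a)
    # positive overlap (stretch) attracts a toward b
    return params.stiffness * overlap * (r / dist)


def _pairwise_forces(population, params: SpringParams, now: float,
                     stream: RandomStream) -> dict[int, np.ndarray]:
    """Sum spring forces over the population's neighbour pairs (vectorized)."""
    ids = population.id_array()
    index = {cid: k for k, cid in enumerate(ids)}
    P = population.position_array()
    pairs = population.neighbour_pairs()
    F = np.zeros_like(P)
    if pairs:
        ia = np.fromiter((index[a] for a, _ in pairs), int, len(pairs))
        ib = np.fromiter((index[b] for _, b in pairs), int, len(pairs))
        r = P[ib] - P[ia]
        dist = np.linalg.norm(r, axis=1)
        coincident = dist < 1e-12
        safe = np.where(coincident, 1.0, dist)
        # per-cell size factor: newborn cells grow from 0.3 to 1 over the
        # ramp; the pairwise rest length is the mean of the two factors
        if population.newborn:
            fac = np.ones(len(ids))
            for cid, t0 in list(population.newborn.items()):
                m = now - t0
                if m >= params.ramp_duration:
                    del population.newborn[cid]
                elif cid in index:
                    fac[index[cid]] = 0.3 + 0.7 * max(m, 0.0) / params.ramp_duration
            s_eff = params.rest_length * 0.5 * (fac[ia] + fac[ib])
        else:
            s_eff = np.full(len(pairs), params.rest_length)
        # repulsion acts against the (possibly reduced) contact length,
        # attraction only beyond the full rest length; for mature pairs the
        # two branches join into the plain linear spring
        mag = params.stiffness * (np.minimum(dist - s_eff, 0.0)
                                  + np.maximum(dist - params.rest_length, 0.0))
        if params.repulsion_only:
            mag = np.minimum(mag, 0.0)
        fvec = np.where((dist > params.cutoff)[:, None], 0.0,
                        (mag / safe)[:, None] * r)
        for k in np.nonzero(coincident)[0]:
            u = stream.unit_vector(P.shape[1])
            fvec[k] = params.stiffness * params.rest_length * u
        np.add.at(F, ia, fvec)
        np.subtract.at(F, ib, fvec)
        # the parent-daughter pair has its own ramp: both halves start small
        # along the division axis, so its rest length runs 0.3 s -> s
        if population.ramp_pairs:
            norm_pairs = {}
            for row, (a, b) in enumerate(pairs):
                norm_pairs[(a, b) if a < b else (b, a)] = row
            expired = []
            for key, t0 in population.ramp_pairs.items():
                m = now - t0
                if m >= params.ramp_duration:
                    expired.append(key)
                    continue
                row = norm_pairs.get(key)
                if row is None:
                    continue
                a, b = key
                rv = population.positions[b] - population.positions[a]
                d = float(np.linalg.norm(rv))
                if d < 1e-12 or d > params.cutoff:
                    continue
                s_pair = params.effective_rest_length(m)
                s_row = float(s_eff[row])
                base = params.stiffness * (min(d - s_row, 0.0)
                                           + max(d - params.rest_length, 0.0))
                ramped = params.stiffness * (d - s_pair)
                if params.repulsion_only:
                    base = min(base, 0.0)
                    ramped = min(ramped, 0.0)
                delta = ((ramped - base) / d) * rv
                F[index[a]] += delta
                F[index[b]] -= delta
            for key in expired:
                del population.ramp_pairs[key]
    return {cid: F[k] for k, cid in enumerate(ids)}


def step_positions(population, params: SpringParams, dt: float, eta: float,
                   stream: RandomStream, now: float = 0.0) -> None:
    """Overdamped forward-Euler update r += (dt/eta) * sum(F).

    Aborts with :class:`StepSizeError` if any displacement exceeds half a
    cell diameter (instability guard).  Mesh-based populations are
    retriangulated lazily after the move.
    """
    if dt <= 0 or eta <= 0:
        raise ValueError("dt and eta must be positive")
    forces = _pairwise_forces(population, params, now, stream)
    limit = 0.5 * params.rest_length
    for cid, f in forces.items():
        disp = (dt / eta) * f
        d = float(np.linalg.norm(disp))
        if d > limit:
            raise StepSizeError(
                f"cell {cid} moved {d:.3f} cell diameters in one step "
                f"(limit {limit}); reduce dt")
        population.positions[cid] = population.positions[cid] + disp
    if isinstance(population, MeshBasedPopulation):
        population.invalidate_mesh()


# ---------------------------------------------------------------------------
# Division and death
# ---------------------------------------------------------------------------

def _split_polygon(mesh: VertexMesh, poly_idx: int):
    """Split a polygon by the line through its centroid perpendicular to its
    long axis.  Returns (new_vertices_list, polygon_a, polygon_b) or None if
    either half would have < 3 vertices."""
    poly = mesh.cell_polygons[poly_idx]
    pts = mesh.vertices[poly]
    _, _, centroid = polygon_measures(pts)
    rel = pts - centroid
    # long axis from the covariance of the vertex cloud
    cov = rel.T @ rel
    evals, evecs = np.linalg.eigh(cov)
    long_axis = evecs[:, int(np.argmax(evals))]
    normal = long_axis  # split plane: {x: (x - centroid).long_axis = 0}
    side = rel @ normal
    side[side == 0] = 1e-14
    n = len(poly)
    cuts = []           # (edge start index, intersection point)
    for i in range(n):
        j = (i + 1) % n
        if (side[i] > 0) != (side[j] > 0):
            t = side[i] / (side[i] - side[j])
            cuts.append((i, pts[i] + t * (pts[j] - pts[i])))
    if len(cuts) != 2:
        return None
    (i0, p0), (i1, p1) = cuts            # i0 < i1 by construction
    base = len(mesh.vertices)
    n0, n1 = base, base + 1
    # A: vertices strictly between the cuts, closed through n1 then n0
    poly_a = [poly[i] for i in range(i0 + 1, i1 + 1)] + [n1, n0]
    # B: the remaining arc, closed through n0 then n1
    poly_b = ([poly[i] for i in range(i1 + 1, n)]
              + [poly[i] for i in range(0, i0 + 1)] + [n0, n1])
    if len(poly_a) < 3 or len(poly_b) < 3:
        return None
    return [p0, p1], poly_a, poly_b


def do_divisions(population, stream: RandomStream, now: float):
    """Divide every cell whose cycle has completed.

    Centre-based: daughter at 0.3 rest lengths in a random direction and the
    spring rest length ramps back up; lattice-based: daughter in a random
    neighbouring site with spare capacity (skipped if none); vertex-based:
    polygon split perpendicular to its long axis.  Returns a list of
    (parent_id, daughter_id) pairs.
    """
    events = []
    ready = [c for c in sorted(population.cells.values(), key=lambda c: c.id)
             if c.ready_to_divide()]
    for cell in ready:
        if isinstance(population, (NodeBasedPopulation, MeshBasedPopulation)):
            u = stream.unit_vector(population.dim)
            pos = population.positions[cell.id] + 0.3 * u
            daughter = population.add_daughter(cell, pos, now, stream)
            cell.age = 0.0
            cell.duration = _draw_duration(cell.cycle_model, stream)
            events.append((cell.id, daughter.id))
        elif isinstance(population, CaBasedPopulation):
            site = population.site_of[cell.id]
            options = [s for s in population.neighbours_of_site(site)
                       if population.spare_capacity(s) > 0]
            if population.spare_capacity(site) > 0:
                options.append(site)
            if not options:
                continue        # stays ready, retried next step
            target = options[int(stream.integer(0, len(options)))]
            cid = population.new_cell_id()
            daughter = Cell(cid, cell.ancestor_id, now, cell.cycle_model,
                            _draw_duration(cell.cycle_model, stream))
            population.cells[cid] = daughter
            population._place(cid, target)
            cell.age = 0.0
            cell.duration = _draw_duration(cell.cycle_model, stream)
            events.append((cell.id, cid))
        elif isinstance(population, VertexBasedPopulation):
            split = _split_polygon(population.mesh, population.polygon_of[cell.id])
            if split is None:
                continue        # deferred
            new_vertices, poly_a, poly_b = split
            mesh = population.mesh
            mesh.vertices = np.vstack([mesh.vertices, np.array(new_vertices)])
            mesh.cell_polygons[population.polygon_of[cell.id]] = poly_a
            # normalize orientations
            from .mesh import polygon_measures as _pm
            if _pm(mesh.vertices[poly_a])[0] < 0:
                mesh.cell_polygons[population.polygon_of[cell.id]] = poly_a[::-1]
            if _pm(mesh.vertices[poly_b])[0] < 0:
                poly_b = poly_b[::-1]
            mesh.cell_polygons.append(poly_b)
            cid = population.new_cell_id()
            daughter = Cell(cid, cell.ancestor_id, now, cell.cycle_model,
                            _draw_duration(cell.cycle_model, stream)
                            if not isinstance(cell.cycle_model, FixedDuration)
                            else cell.cycle_model.duration)
            population.cells[cid] = daughter
            population.polygon_of[cid] = len(mesh.cell_polygons) - 1
            cell.age = 0.0
            events.append((cell.id, cid))
        else:
            raise TypeError(f"division not supported for {type(population)}")
    return events


def apply_oxygen_rule(population, interp, model: OxygenDependent, dt: float):
    """Gate cycling on interpolated oxygen and accumulate death timers.

    `interp` maps a position to a concentration (e.g. a
    :class:`~tissuesim.pde.FieldInterpolator`).  Strictly above c_quiescent
    the cell cycles; in (c_death, c_quiescent] it is arrested with its age
    frozen; at or below c_death the low-oxygen timer accumulates and the cell
    dies once it exceeds tau_death.  Returns (labels, removed_ids).
    """
    labels = {}
    removed = []
    for cell in sorted(population.living_cells(), key=lambda c: c.id):
        pos = population.positions[cell.id]
        c = interp(pos)
        cell.data["oxygen"] = c
        if c > model.c_quiescent:
            cell.arrested = False
            cell.low_oxygen_timer = 0.0
            labels[cell.id] = "cycling"
        elif c > model.c_death:
            cell.arrested = True
            cell.low_oxygen_timer = 0.0
            labels[cell.id] = "quiescent"
        else:
            cell.arrested = True
            cell.low_oxygen_timer += dt
            labels[cell.id] = "hypoxic"
            if cell.low_oxygen_timer > model.tau_death:
                cell.alive = False
                removed.append((cell.id, pos.copy()))
    for cid, _ in removed:
        population.remove_cell(cid)
    return labels, removed


# ---------------------------------------------------------------------------
# Cellular Potts dynamics
# ---------------------------------------------------------------------------

def potts_hamiltonian(population: PottsPopulation,
                      params: PottsParams | None = None) -> float:
    """H = sum_{unequal-spin neighbour site pairs} J + sum_cells lambda (a-A)^2."""
    params = params or population.params
    spins = population.spins
    nx, ny = spins.shape
    offsets = [(1, 0), (0, 1)]
    if params.neighbourhood == "moore":
        offsets += [(1, 1), (1, -1)]
    H = 0.0
    for di, dj in offsets:
        for i in range(nx):
            i2 = i + di
            if not 0 <= i2 < nx:
                continue
            for j in range(ny):
                j2 = j + dj
                if not 0 <= j2 < ny:
                    continue
                s1, s2 = int(spins[i, j]), int(spins[i2, j2])
                if s1 != s2:
                    H += params.j_between(population.type_of(s1),
                                          population.type_of(s2))
    lam = params.area_stiffness
    A = params.target_area
    for cid in population.cells:
        if population.areas.get(cid, 0) == 0:
            raise ValueError(f"cell {cid} has no lattice sites")
        H += lam * (population.areas[cid] - A) ** 2
    # spins referencing unknown cells
    for s in np.unique(spins):
        if s != population.MEDIUM and int(s) not in population.cells:
            raise ValueError(f"spin {int(s)} references unknown cell")
    return float(H)


def _potts_delta_h(population: PottsPopulation, params: PottsParams,
                   site: tuple, new_spin: int) -> float:
    """Energy change of copying `new_spin` into `site` (incremental)."""
    spins = population.spins
    nx, ny = spins.shape
    old_spin = int(spins[site])
    if old_spin == new_spin:
        return 0.0
    dH = 0.0
    t_old, t_new = population.type_of(old_spin), population.type_of(new_spin)
    for di, dj in population.neighbour_offsets():
        i2, j2 = site[0] + di, site[1] + dj
        if not (0 <= i2 < nx and 0 <= j2 < ny):
            continue
        s_nb = int(spins[i2, j2])
        t_nb = population.type_of(s_nb)
        if s_nb != old_spin:
            dH -= params.j_between(t_old, t_nb)
        if s_nb != new_spin:
            dH += params.j_between(t_new, t_nb)
    lam, A = params.area_stiffness, params.target_area
    if old_spin != population.MEDIUM:
        a = population.areas[old_spin]
        dH += lam * ((a - 1 - A) ** 2 - (a - A) ** 2)
    if new_spin != population.MEDIUM:
        a = population.areas[new_spin]
        dH += lam * ((a + 1 - A) ** 2 - (a - A) ** 2)
    return float(dH)


def metropolis_accept(dH: float, temperature: float,
                      stream: RandomStream) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dH/T)).

    At T = 0 a move is accepted iff it does not increase the energy.
    """
    if dH <= 0:
        return True
    if temperature == 0:
        return False
    return bool(stream.uniform() < np.exp(-dH / temperature))


def potts_mc_sweep(population: PottsPopulation, params: PottsParams,
                   stream: RandomStream) -> int:
    """One Metropolis sweep: N_sites proposed neighbour-spin copies.

    Acceptance min(1, exp(-dH/T)); at T=0 accept iff dH <= 0.  A move that
    would annihilate a cell's last site is rejected.  Returns the number of
    accepted moves.
    """
    spins = population.spins
    nx, ny = spins.shape
    offsets = population.neighbour_offsets()
    accepted = 0
    for _ in range(nx * ny):
        i = int(stream.integer(0, nx))
        j = int(stream.integer(0, ny))
        di, dj = offsets[int(stream.integer(0, len(offsets)))]
        i2, j2 = i + di, j + dj
        if not (0 <= i2 < nx and 0 <= j2 < ny):
            continue
        new_spin = int(spins[i2, j2])
        old_spin = int(spins[i, j])
        if new_spin == old_spin:
            continue
        if old_spin != population.MEDIUM and population.areas[old_spin] <= 1:
            continue   # never annihilate a cell
        dH = _potts_delta_h(population, params, (i, j), new_spin)
        if metropolis_accept(dH, params.temperature, stream):
            spins[i, j] = new_spin
            if old_spin != population.MEDIUM:
                population.areas[old_spin] -= 1
            if new_spin != population.MEDIUM:
                population.areas[new_spin] += 1
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# Vertex dynamics
# ---------------------------------------------------------------------------

def _edge_gammas(mesh: VertexMesh, params: VertexForceParams) -> dict:
    out = {}
    for e, cells in mesh.edges().items():
        out[e] = (params.gamma_boundary if len(cells) == 1
                  else params.gamma_interior)
    return out


def vertex_energy(mesh: VertexMesh, params: VertexForceParams) -> float:
    """E = sum_cells [K_A (A-A0)^2 + K_P (P-P0)^2] + sum_edges gamma * length."""
    E = 0.0
    for poly in mesh.cell_polygons:
        A, P, _ = polygon_measures(mesh.vertices[poly])
        E += (params.area_stiffness * (A - params.target_area) ** 2
              + params.perimeter_stiffness * (P - params.target_perimeter) ** 2)
    for (a, b), gamma in _edge_gammas(mesh, params).items():
        if gamma:
            E += gamma * float(np.linalg.norm(mesh.vertices[a] - mesh.vertices[b]))
    return E


def vertex_force(mesh: VertexMesh, params: VertexForceParams) -> np.ndarray:
    """F_v = -dE/dv per vertex, assembled from analytic shape gradients."""
    F = np.zeros_like(mesh.vertices)
    for poly in mesh.cell_polygons:
        pts = mesh.vertices[poly]
        A, P, _ = polygon_measures(pts)
        cA = 2 * params.area_stiffness * (A - params.target_area)
        cP = 2 * params.perimeter_stiffness * (P - params.target_perimeter)
        for local, vid in enumerate(poly):
            dA, dP = shape_gradients(pts, local)
            F[vid] -= cA * dA + cP * dP
    for (a, b), gamma in _edge_gammas(mesh, params).items():
        if gamma:
            d = mesh.vertices[a] - mesh.vertices[b]
            L = float(np.linalg.norm(d))
            if L > 0:
                F[a] -= gamma * d / L
                F[b] += gamma * d / L
    return F


def vertex_t1_swaps(mesh: VertexMesh, params: VertexForceParams,
                    threshold: float | None = None) -> int:
    """Perform T1 swaps on interior edges shorter than the threshold.

    Default threshold 0.01*sqrt(A0); the swapped edge re-expands
    perpendicular to its old direction at 1.5x the threshold.  Returns the
    number of swaps performed.
    """
    if threshold is None:
        threshold = 0.01 * np.sqrt(params.target_area)
    n_swaps = 0
    edges = mesh.edges()
    for (a, b), cells in edges.items():
        if len(cells) != 2:
            continue
        va, vb = mesh.vertices[a], mesh.vertices[b]
        L = float(np.linalg.norm(va - vb))
        if L >= threshold or L == 0:
            continue
        P, Q = cells
        if len(mesh.cell_polygons[P]) <= 3 or len(mesh.cell_polygons[Q]) <= 3:
            continue
        # cells sharing only vertex a / only vertex b
        Ra = [c for c, poly in enumerate(mesh.cell_polygons)
              if a in poly and b not in poly]
        Rb = [c for c, poly in enumerate(mesh.cell_polygons)
              if b in poly and a not in poly]
        mid = 0.5 * (va + vb)
        u = (vb - va) / L
        perp = np.array([-u[1], u[0]])
        mesh.vertices[a] = mid + 0.75 * threshold * perp
        mesh.vertices[b] = mid - 0.75 * threshold * perp
        # P keeps a only, Q keeps b only; Ra cells gain b after a, Rb gain a after b
        polyP = mesh.cell_polygons[P]
        polyQ = mesh.cell_polygons[Q]
        mesh.cell_polygons[P] = [v for v in polyP if v != b]
        mesh.cell_polygons[Q] = [v for v in polyQ if v != a]
        for c in Ra:
            poly = mesh.cell_polygons[c]
            k = poly.index(a)
            poly.insert(k + 1, b)
        for c in Rb:
            poly = mesh.cell_polygons[c]
            k = poly.index(b)
            poly.insert(k + 1, a)
        # re-orient if needed
        for c in {P, Q, *Ra, *Rb}:
            area, _, _ = polygon_measures(mesh.vertices[mesh.cell_polygons[c]])
            if area < 0:
                mesh.cell_polygons[c] = mesh.cell_polygons[c][::-1]
        n_swaps += 1
        break   # edges() is stale after a swap; rescan next call
    return n_swaps


def step_vertex_positions(population: VertexBasedPopulation, dt: float,
                          eta: float) -> None:
    """Overdamped vertex update plus T1 maintenance."""
    F = vertex_force(population.mesh, population.params)
    population.mesh.vertices = population.mesh.vertices + (dt / eta) * F
    vertex_t1_swaps(population.mesh, population.params)


# ---------------------------------------------------------------------------
# Lineage, surfaces, rules, killers, CA migration
# ---------------------------------------------------------------------------

def track_ancestors(population) -> Counter:
    """Living-cell count per ancestor id (a partition of the living cells)."""
    return Counter(c.ancestor_id for c in population.living_cells())


def is_monoclonal(population, region_predicate=None) -> bool:
    """True iff exactly one ancestor is present (in the region, if given)."""
    ancestors = set()
    for c in population.living_cells():
        if region_predicate is not None:
            pos = population.positions[c.id]
            if not region_predicate(pos):
                continue
        ancestors.add(c.ancestor_id)
    return len(ancestors) == 1


def project_to_surface(population, surface) -> None:
    """Snap every cell centre to its closest point on the surface."""
    for cid in population.positions:
        population.positions[cid] = surface.project(population.positions[cid])
    if isinstance(population, MeshBasedPopulation):
        population.invalidate_mesh()


def wnt_proliferation_rule(cell: Cell, z: float, crypt_length: float,
                           threshold: float) -> bool:
    """Position-dependent Wnt proxy: wnt = clamp(1 - z/L, 0, 1).

    The cell cycles iff wnt is strictly above the threshold (ties arrest).
    `z` is height above the crypt base.
    """
    if crypt_length <= 0:
        raise ValueError("crypt length must be positive")
    wnt = min(1.0, max(0.0, 1.0 - z / crypt_length))
    cell.data["wnt"] = wnt
    cycling = wnt > threshold
    cell.arrested = not cycling
    return cycling


def sloughing_killer(population, boundary_predicate) -> list[int]:
    """Remove every cell whose position satisfies the predicate."""
    doomed = [cid for cid, pos in sorted(population.positions.items())
              if boundary_predicate(pos)]
    for cid in doomed:
        population.cells[cid].alive = False
        population.remove_cell(cid)
    return doomed


def ca_migration_step(population: CaBasedPopulation,
                      stream: RandomStream) -> int:
    """Random-sequential CA migration.

    Each cell, in shuffled order, attempts a move to a uniformly chosen
    neighbour site and succeeds iff that site has spare capacity.  Returns
    the number of successful moves; total cell count is conserved.
    """
    ids = sorted(population.cells)
    stream.shuffle(ids)
    moved = 0
    for cid in ids:
        site = population.site_of[cid]
        nbs = population.neighbours_of_site(site)
        target = nbs[int(stream.integer(0, len(nbs)))]
        if population.spare_capacity(target) > 0:
            population.move_cell(cid, target)
            moved += 1
    return moved


# ---------------------------------------------------------------------------
# Simulation engine
# ---------------------------------------------------------------------------

@dataclass
class OxygenCoupling:
    """Quasi-steady oxygen: elliptic re-solve at a fixed coupling interval.

    The boundary condition is a fixed concentration at the (moving) tissue
    surface: every mesh node farther than `dirichlet_margin` from the nearest
    living cell is clamped to `boundary_value`, along with the mesh rim.
    Uptake (linear in c) is supported on elements whose centroid lies within
    one cell radius of a living cell centre.
    """
    pde_mesh: object                  # SimplexMesh
    diffusivity: float = 1.0          # cell-diameter^2 / h
    uptake_rate: float = 0.07         # 1/h where tissue is present
    boundary_value: float = 1.0
    coupling_interval: float | None = None   # hours; None = every step
    cell_radius: float = 0.75
    dirichlet_margin: float = 1.0     # cell diameters
    model: OxygenDependent = dataclass_field(default_factory=OxygenDependent)

    def __post_init__(self):
        from . import pde as _pde
        self._pde = _pde
        self._centroids = self.pde_mesh.centroids()
        self.field = None
        self.interpolator = None
        self._last_solve = -np.inf

    def solve(self, population) -> None:
        from scipy.spatial import cKDTree
        mesh = self.pde_mesh
        pts = population.position_array()
        dim = mesh.points.shape[1]
        tree = cKDTree(pts[:, :dim])
        d_el, _ = tree.query(self._centroids)
        k = np.where(d_el <= self.cell_radius, self.uptake_rate, 0.0)
        d_node, _ = tree.query(mesh.points)
        # clamp only nodes outside the tissue: far from every cell AND
        # beyond the colony extent (an interior void is not bathed in
        # oxygen, so it must not be clamped)
        centroid = pts[:, :dim].mean(axis=0)
        r_live = np.linalg.norm(pts[:, :dim] - centroid, axis=1).max()
        r_node = np.linalg.norm(mesh.points - centroid, axis=1)
        exterior = (d_node > self.dirichlet_margin) & (r_node > r_live)
        dirichlet = {int(i): self.boundary_value
                     for i in np.nonzero(exterior)[0]}
        for i in mesh.boundary_node_ids:
            dirichlet[int(i)] = self.boundary_value
        problem = self._pde.ReactionDiffusionProblem(
            mesh, diffusivity=self.diffusivity, uptake=k,
            source=0.0, dirichlet=dirichlet)
        self.field = self._pde.solve_steady(problem)
        self.interpolator = self._pde.FieldInterpolator(self.field)

    def maybe_solve(self, population, now: float) -> None:
        interval = self.coupling_interval
        if (self.field is None or interval is None
                or now - self._last_solve >= interval - 1e-12):
            self.solve(population)
            self._last_solve = now


class Simulator:
    """Fixed-order explicit time stepping over a cell population.

    Per step: (1) cycle/oxygen/Wnt state update, (2) signalling layer,
    (3) deaths/killers, (4) divisions, (5) forces + position update
    (+ surface projection), (6) PDE re-solve at the coupling interval,
    (7) scheduled output.  Entirely reproducible from (config, seed).
    """

    def __init__(self, population, *, dt: float = 1.0 / 120.0,
                 end_time: float = 1.0, eta: float = 1.0,
                 spring_params: SpringParams | None = None,
                 stream: RandomStream | None = None,
                 oxygen: OxygenCoupling | None = None,
                 signalling=None,
                 killers: list | None = None,
                 surface=None,
                 wnt: dict | None = None,    # {"length": L, "threshold": w*}
                 motility_sigma: float = 0.0,   # diam/sqrt(h), Brownian motility
                 writers: list | None = None,
                 output_interval: float | None = None,
                 start_time: float = 0.0):
        self.population = population
        self.dt = dt
        self.end_time = end_time
        self.eta = eta
        self.spring_params = spring_params or SpringParams()
        self.stream = stream or RandomStream(0)
        self.oxygen = oxygen
        self.signalling = signalling
        self.killers = killers or []
        self.surface = surface
        self.wnt = wnt
        self.motility_sigma = motility_sigma
        self.writers = writers or []
        self.output_interval = output_interval
        self.time = start_time
        # step times are computed as base_time + k*dt (never accumulated),
        # so a resumed run reproduces the uninterrupted time sequence bit
        # for bit; checkpoints are taken between steps
        self.base_time = start_time
        self.step_index = 0
        self.events: list[dict] = []
        self.phase_timings: dict[str, float] = {}
        self._last_output = -np.inf

    # -- individual phases ---------------------------------------------------

    def _tissue_extent(self):
        """(centroid, max radius) of the living cells, for event context."""
        pts = self.population.position_array()
        centroid = pts.mean(axis=0)
        R = float(np.linalg.norm(pts - centroid, axis=1).max())
        return centroid, R

    def _phase_cycle(self):
        pop = self.population
        if self.oxygen is not None and self.oxygen.interpolator is not None:
            _, removed = apply_oxygen_rule(pop, self.oxygen.interpolator,
                                           self.oxygen.model, self.dt)
            if removed:
                centroid, R = self._tissue_extent()
                for cid, pos in removed:
                    self.events.append({
                        "type": "death", "time": self.time, "cell": cid,
                        "position": pos,
                        "radius": float(np.linalg.norm(pos - centroid)),
                        "tissue_radius": R})
        if self.wnt is not None:
            for cell in pop.living_cells():
                z = self.wnt["height"](pop.positions[cell.id])
                wnt_proliferation_rule(cell, z, self.wnt["length"],
                                       self.wnt["threshold"])
        for cell in pop.living_cells():
            if not cell.arrested:
                cell.age += self.dt

    def _phase_signalling(self):
        if self.signalling is not None:
            self.signalling.step(self.population, self.dt)

    def _phase_killers(self):
        for killer in self.killers:
            for cid in sloughing_killer(self.population, killer):
                self.events.append({"type": "slough", "time": self.time,
                                    "cell": cid})

    def _phase_divisions(self):
        pop = self.population
        divisions = do_divisions(pop, self.stream, self.time)
        if divisions and hasattr(pop, "positions"):
            centroid, R = self._tissue_extent()
        for parent, daughter in divisions:
            rec = {"type": "division", "time": self.time,
                   "parent": parent, "daughter": daughter}
            if hasattr(pop, "positions"):
                pos = pop.positions[parent].copy()
                rec["position"] = pos
                rec["radius"] = float(np.linalg.norm(pos - centroid))
                rec["tissue_radius"] = R
            self.events.append(rec)
            if self.signalling is not None:
                self.signalling.on_division(parent, daughter)

    def _phase_movement(self):
        pop = self.population
        if isinstance(pop, (NodeBasedPopulation, MeshBasedPopulation)):
            step_positions(pop, self.spring_params, self.dt, self.eta,
                           self.stream, now=self.time)
            if self.motility_sigma > 0:
                amp = self.motility_sigma * np.sqrt(2.0 * self.dt)
                ids = pop.id_array()
                kicks = self.stream.normal(0.0, amp, size=(len(ids), pop.dim))
                for k, cid in enumerate(ids):
                    pop.positions[cid] = pop.positions[cid] + kicks[k]
                if isinstance(pop, MeshBasedPopulation):
                    pop.invalidate_mesh()
            if self.surface is not None:
                project_to_surface(pop, self.surface)
        elif isinstance(pop, VertexBasedPopulation):
            step_vertex_positions(pop, self.dt, self.eta)
        elif isinstance(pop, CaBasedPopulation):
            ca_migration_step(pop, self.stream)
        elif isinstance(pop, PottsPopulation):
            potts_mc_sweep(pop, pop.params, self.stream)

    def _phase_pde(self):
        if self.oxygen is not None:
            self.oxygen.maybe_solve(self.population, self.time)

    def _phase_output(self, force=False):
        if self.output_interval is None and not force:
            return
        if (force or self.time - self._last_output
                >= (self.output_interval or 0) - 1e-12):
            for w in self.writers:
                w(self)
            self._last_output = self.time

    # -- driver ----------------------------------------------------------------

    def _timed(self, name, fn):
        import time as _time
        t0 = _time.perf_counter()
        try:
            fn()
        except Exception as e:
            if getattr(e, "_has_step_context", False):
                raise
            try:
                wrapped = type(e)(
                    f"step {self.step_index} ({name} phase): {e}")
            except Exception:
                wrapped = RuntimeError(
                    f"step {self.step_index} ({name} phase): {e}")
            wrapped._has_step_context = True
            raise wrapped from e
        finally:
            self.phase_timings[name] = (self.phase_timings.get(name, 0.0)
                                        + _time.perf_counter() - t0)

    def step(self):
        self._timed("cycle", self._phase_cycle)
        self._timed("signalling", self._phase_signalling)
        self._timed("killers", self._phase_killers)
        self._timed("divisions", self._phase_divisions)
        self._timed("movement", self._phase_movement)
        self.step_index += 1
        t1 = self.base_time + self.step_index * self.dt
        eps = 1e-9 * max(1.0, abs(self.end_time))
        if t1 > self.end_time + eps:       # truncated (non-grid) final step
            t1 = self.end_time
        self.time = t1
        self._timed("pde", self._phase_pde)
        self._timed("output", self._phase_output)

    def run(self):
        """Run to end_time; returns (times, cell counts) trajectory."""
        if self.oxygen is not None:
            self.oxygen.maybe_solve(self.population, self.time)
        self._phase_output(force=True)
        times = [self.time]
        counts = [self.population.n_cells]
        eps = 1e-9 * max(1.0, abs(self.end_time))
        while self.time < self.end_time - eps:
            self.step()
            times.append(self.time)
            counts.append(self.population.n_cells)
        self._phase_output(force=True)
        return np.array(times), np.array(counts)


def run_simulation(simulator: Simulator):
    """Convenience driver; returns (times, counts, events)."""
    times, counts = simulator.run()
    return times, counts, simulator.events
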