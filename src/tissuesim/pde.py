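"""P1 finite-element reaction-diffusion solves on simplex meshes.

Solves the linear problem

    -div(D grad c) + k c = f        (steady)
    dc/dt = div(D grad c) - k c + f (parabolic, implicit Euler)

on triangles (2D) or tetrahedra (3D), with Dirichlet values on a node set
and the natural zero-flux condition elsewhere.  Used for the oxygen field
around growing cell populations and reused by the cardiac solver's
mesh-based diffusion path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import SimplexMesh

__all__ = ["ReactionDiffusionProblem", "ScalarField",
           "solve_steady", "step_parabolic", "interpolate",
           "assemble_stiffness", "assemble_mass", "FieldError"]


class FieldError(ValueError):
    pass


@dataclass
class ScalarField:
    """Nodal scalar values on a simplex mesh."""
    mesh: SimplexMesh
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_nodes,):
            raise FieldError("one value per mesh node required")
        if not np.all(np.isfinite(self.values)):
            raise FieldError("non-finite field values")


@dataclass
class ReactionDiffusionProblem:
    """-div(D grad c) + k c = f with Dirichlet + zero-flux boundaries.

    D may be a scalar or per-element array; k likewise (uptake is often
    supported only on elements overlapping the tissue).  f is per-node.
    """
    mesh: SimplexMesh
    diffusivity: float | np.ndarray = 1.0
    uptake: float | np.ndarray = 0.0
    source: float | np.ndarray = 0.0
    dirichlet: dict = field(default_factory=dict)   # node id -> value

    def per_element(self, v) -> np.ndarray:
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return np.full(self.mesh.n_elements, float(arr))
        if arr.shape != (self.mesh.n_elements,):
            raise FieldError("per-element array has wrong length")
        return arr

    def per_node(self, v) -> np.ndarray:
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return np.full(self.mesh.n_nodes, float(arr))
        if arr.shape != (self.mesh.n_nodes,):
            raise FieldError("per-node array has wrong length")
        return arr


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _element_geometry(mesh: SimplexMesh):
    """Per-element measures and P1 basis gradients.

    Returns (measures[ne], grads[ne, dim+1, dim]).
    """
    pts = mesh.points
    els = mesh.elements
    dim = mesh.dim
    v = pts[els[:, 1:]] - pts[els[:, :1]]          # (ne, dim, dim)
    det = np.linalg.det(v)
    from math import factorial
    measures = det / factorial(dim)
    vinv = np.linalg.inv(v)                        # rows map to local coords
    # gradients of barycentric coords lambda_1..lambda_dim are columns of vinv
    g = np.transpose(vinv, (0, 2, 1))              # (ne, dim, dim)
    g0 = -g.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g], axis=1)        # (ne, dim+1, dim)
    return measures, grads


def assemble_stiffness(mesh: SimplexMesh, diffusivity) -> sp.csr_matrix:
    """Stiffness matrix of -div(D grad .) (symmetric positive semi-definite)."""
    measures, grads = _element_geometry(mesh)
    D = np.asarray(diffusivity, dtype=float)
    if D.ndim == 0:
        D = np.full(mesh.n_elements, float(D))
    ne, nv, _ = grads.shape
    local = np.einsum("e,eid,ejd->eij", D * measures, grads, grads)
    rows = np.repeat(mesh.elements, nv, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, nv)).ravel()
    K = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


def assemble_mass(mesh: SimplexMesh, coeff=1.0, lumped: bool = False) -> sp.csr_matrix:
    """Mass matrix with per-element coefficient (consistent or lumped)."""
    measures, _ = _element_geometry(mesh)
    c = np.asarray(coeff, dtype=float)
    if c.ndim == 0:
        c = np.full(mesh.n_elements, float(c))
    nv = mesh.dim + 1
    if lumped:
        diag = np.zeros(mesh.n_nodes)
        np.add.at(diag, mesh.elements.ravel(),
                  np.repeat(c * measures / nv, nv))
        return sp.diags(diag).tocsr()
    # consistent P1 mass: (|T|/((d+1)(d+2))) * (1 + delta_ij)
    base = (np.ones((nv, nv)) + np.eye(nv)) / ((nv) * (nv + 1))
    local = (c * measures)[:, None, None] * base
    rows = np.repeat(mesh.elements, nv, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, nv)).ravel()
    M = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return M.tocsr()


def _apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dirichlet: dict):
    """Impose Dirichlet rows by elimination, keeping symmetry of the free block."""
    n = A.shape[0]
    fixed = np.array(sorted(dirichlet), dtype=int)
    vals = np.array([dirichlet[i] for i in fixed], dtype=float)
    x_d = np.zeros(n)
    x_d[fixed] = vals
    b = b - A @ x_d
    free = np.setdiff1d(np.arange(n), fixed)
    return A[free][:, free].tocsc(), b[free], free, fixed, vals


def solve_steady(problem: ReactionDiffusionProblem) -> ScalarField:
    """Galerkin P1 solution of the steady problem.

    Dirichlet node values are reproduced exactly.  A problem with no
    Dirichlet nodes and no uptake is singular and rejected.
    """
    mesh = problem.mesh
    k = problem.per_element(problem.uptake)
    if not problem.dirichlet and not np.any(k > 0):
        raise FieldError("steady problem is singular: no Dirichlet nodes "
                         "and no uptake term")
    K = assemble_stiffness(mesh, problem.diffusivity)
    A = K + assemble_mass(mesh, k)
    f = problem.per_node(problem.source)
    b = assemble_mass(mesh, 1.0) @ f
    Af, bf, free, fixed, vals = _apply_dirichlet(A, b, problem.dirichlet)
    x = np.zeros(mesh.n_nodes)
    x[fixed] = vals
    if len(free):
        x[free] = spla.spsolve(Af, bf)
    if not np.all(np.isfinite(x)):
        raise FieldError("linear solve failed (non-finite solution)")
    return ScalarField(mesh, x)


def step_parabolic(problem: ReactionDiffusionProblem, fld: ScalarField,
                   dt: float) -> ScalarField:
    """One implicit-Euler step of dc/dt = div(D grad c) - k c + f."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    mesh = problem.mesh
    M = assemble_mass(mesh, 1.0)
    K = assemble_stiffness(mesh, problem.diffusivity)
    R = assemble_mass(mesh, problem.per_element(problem.uptake))
    f = problem.per_node(problem.source)
    A = (M + dt * (K + R)).tocsr()
    b = M @ fld.values + dt * (M @ f)
    if problem.dirichlet:
        Af, bf, free, fixed, vals = _apply_dirichlet(A, b, problem.dirichlet)
        x = np.zeros(mesh.n_nodes)
        x[fixed] = vals
        x[free] = spla.spsolve(Af, bf)
    else:
        x = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(x)):
        raise FieldError("parabolic step failed (non-finite solution)")
    return ScalarField(mesh, x)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

class FieldInterpolator:
    """Barycentric point evaluation inside the mesh's own elements.

    Candidate elements come from a KD-tree over element centroids; the
    containing element is the one whose barycentric coordinates of the query
    are all >= -1e-12.  This honours the mesh's actual triangulation even
    where a fresh Delaunay would break cocircular ties differently.
    """

    def __init__(self, field: ScalarField):
        from scipy.spatial import cKDTree
        self.field = field
        mesh = field.mesh
        self._mesh = mesh
        cent = mesh.centroids()
        self._tree = cKDTree(cent)
        # inverse edge matrices for barycentric coords
        pts = mesh.points
        v = pts[mesh.elements[:, 1:]] - pts[mesh.elements[:, :1]]
        self._vinv = np.linalg.inv(v)
        self._origin = pts[mesh.elements[:, 0]]

    def _bary(self, k: int, p: np.ndarray) -> np.ndarray:
        lam = (p - self._origin[k]) @ self._vinv[k]
        return np.append(1 - lam.sum(), lam)

    def __call__(self, point) -> float:
        p = np.asarray(point, dtype=float)
        k_query = min(32, self._mesh.n_elements)
        _, cand = self._tree.query(p, k=k_query)
        cand = np.atleast_1d(cand)
        for k in cand:
            w = self._bary(int(k), p)
            if np.all(w >= -1e-12):
                return float(w @ self.field.values[self._mesh.elements[int(k)]])
        # exhaustive fallback before declaring the point outside
        for k in range(self._mesh.n_elements):
            w = self._bary(k, p)
            if np.all(w >= -1e-12):
                return float(w @ self.field.values[self._mesh.elements[k]])
        raise FieldError(f"point {point} lies outside the mesh support")


def interpolate(field: ScalarField, point) -> float:
    """Barycentric interpolation of `field` at one point.

    Note: builds a point-location structure per call; use
    :class:`FieldInterpolator` for repeated queries.
    """
    return FieldInterpolator(field)(point)
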