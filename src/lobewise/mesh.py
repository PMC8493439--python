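"""Triangulated surface meshes and smooth random fields on them.

A :class:`SurfaceMesh` carries vertex coordinates, triangular faces and the
edge-connected vertex adjacency used both for cluster finding and for
generating spatially smooth noise (iterated neighbor-mean smoothing of i.i.d.
Gaussian vertex noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass
class SurfaceMesh:
    """Vertices, faces, and derived edge-connected adjacency."""

    vertices: np.ndarray
    faces: np.ndarray
    adjacency: sparse.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("faces index nonexistent vertices")
        ii, jj = [], []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            ii.append(self.faces[:, a])
            jj.append(self.faces[:, b])
        i = np.concatenate(ii + jj)
        j = np.concatenate(jj + ii)
        adj = sparse.coo_matrix((np.ones_like(i), (i, j)), shape=(n, n))
        adj = (adj + adj.T).tolil()
        adj.setdiag(0)  # degenerate faces must not create self-edges
        adj = adj.tocsr()
        adj.eliminate_zeros()
        adj.data[:] = 1
        self.adjacency = adj

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Neighbors of each vertex as index arrays."""
        a = self.adjacency
        return [a.indices[a.indptr[v] : a.indptr[v + 1]] for v in range(a.shape[0])]

    def vertex_areas(self) -> np.ndarray:
        """One third of the summed area of each vertex's incident faces (mm^2)."""
        v = self.vertices
        tri = v[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        face_area = 0.5 * np.linalg.norm(cross, axis=1)
        areas = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(areas, self.faces[:, k], face_area / 3.0)
        return areas

    def smoothing_operator(self, include_self: bool = True) -> sparse.csr_matrix:
        """Row-stochastic one-step neighbor-mean smoothing matrix."""
        a = self.adjacency.astype(float)
        if include_self:
            a = a + sparse.identity(self.n_vertices, format="csr")
        deg = np.asarray(a.sum(axis=1)).ravel()
        inv = sparse.diags(1.0 / deg)
        return (inv @ a).tocsr()


def icosphere(subdivisions: int = 3, radius: float = 50.0) -> SurfaceMesh:
    """Icosphere mesh; 3 subdivisions gives 642 vertices."""
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def path_mesh(n: int) -> SurfaceMesh:
    """A degenerate chain mesh v0-v1-...-v(n-1) for tiny exact tests."""
    verts = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    faces = np.array([[i, i + 1, i] for i in range(n - 1)], dtype=int)
    return SurfaceMesh(verts, faces)


def smooth_field_basis(mesh: SurfaceMesh, iterations: int) -> np.ndarray:
    """Dense matrix M mapping i.i.d. N(0,1) vertex noise to a smooth field
    with unit variance at every vertex.

    M = normalize_rows(S^k) where S is the neighbor-mean operator; row
    normalization makes Var[(M eps)_v] = 1 exactly for every vertex.
    """
    n = mesh.n_vertices
    M = np.eye(n)
    if iterations > 0:
        S = mesh.smoothing_operator().toarray()
        for _ in range(iterations):
            M = S @ M
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    return M / norms


def smooth_noise(
    mesh: SurfaceMesh,
    n_fields: int,
    iterations: int,
    rng: np.random.Generator,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """(n_fields, n_vertices) smooth Gaussian fields, unit variance per vertex."""
    if basis is None:
        basis = smooth_field_basis(mesh, iterations)
    eps = rng.standard_normal((n_fields, mesh.n_vertices))
    return eps @ basis.T


def lag1_neighbor_correlation(mesh: SurfaceMesh, fields: np.ndarray) -> float:
    """Mean correlation of field values across mesh edges (smoothness proxy)."""
    f = np.atleast_2d(fields)
    f = f - f.mean(axis=1, keepdims=True)
    sd = f.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = f / sd
    upper = sparse.triu(mesh.adjacency.tocoo(), k=1).tocoo()
    i, j = upper.row, upper.col
    return float(np.mean(z[:, i] * z[:, j]))
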