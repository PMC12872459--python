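"""Triangle-mesh geometry: the substrate for all surface-based computation.

A cortical (sub)surface is represented as a :class:`TriangleMesh`.  This module
provides the discrete Laplace-Beltrami operator (cotangent stiffness with a
lumped barycentric mass matrix), graph geodesic distances, and submesh
extraction against a vertex mask.

Geodesics are shortest paths along the mesh edge graph (Dijkstra with
Euclidean edge weights).  This upper-bounds exact polyhedral geodesics; all
downstream uses (sampling extents, searchlight chunks, topographic
coordinates) are ordinal or threshold-based, for which the edge-graph
approximation is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "TriangleMesh",
    "SubsurfaceSelection",
    "GeodesicField",
    "cotangent_operators",
    "geodesic_distances",
    "geodesic_matrix",
    "build_submesh",
    "vertex_adjacency",
]


@dataclass
class TriangleMesh:
    """Triangulated surface patch.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex-index triples.
    hemisphere : (n,) int array, optional
        Per-vertex hemisphere tag (e.g. 0 = left, 1 = right).  Sampling
        extents and other within-hemisphere quantities never cross labels.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise ValueError("non-finite vertex coordinates")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        if self.faces.size and self.faces.min() < 0:
            raise ValueError("negative face index")
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
            if len(self.hemisphere) != len(self.vertices):
                raise ValueError("hemisphere labels must match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())


@dataclass
class SubsurfaceSelection:
    """Bookkeeping for a submesh cut from a parent mesh."""

    parent_indices: np.ndarray  # submesh vertex -> parent vertex (injective)
    mask_name: str = ""

    def __post_init__(self) -> None:
        self.parent_indices = np.asarray(self.parent_indices, dtype=np.int64)
        if len(np.unique(self.parent_indices)) != len(self.parent_indices):
            raise ValueError("parent_indices must be injective")


@dataclass
class GeodesicField:
    """Distances (mm) from a seed set, one value per vertex."""

    distances: np.ndarray
    seed_indices: np.ndarray
    has_unreachable: bool = field(default=False)


def cotangent_operators(mesh: TriangleMesh):
    """Cotangent stiffness matrix and lumped (barycentric) mass weights.

    Returns
    -------
    stiffness : (n, n) sparse CSR, symmetric positive semi-definite
        Off-diagonal ``L[i, j] = -(cot a + cot b) / 2`` over the one or two
        angles opposite edge (i, j); rows sum to zero (constant functions are
        in the kernel).  The quadratic form ``x' L x`` is the discrete
        Dirichlet energy.
    mass : (n,) float array
        One third of the incident face area per vertex, in mm^2.

    Raises
    ------
    ValueError
        On non-finite coordinates or a degenerate (zero-area) face; the
        message names the first offending face index.
    """
    v = mesh.vertices
    f = mesh.faces
    n = mesh.n_vertices
    areas = mesh.face_areas()
    bad = np.flatnonzero(areas <= 1e-14)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) face at index {bad[0]}")

    rows, cols, vals = [], [], []
    mass = np.zeros(n)
    np.add.at(mass, f.ravel(), np.repeat(areas / 3.0, 3))

    # For corner k of each face, the cotangent of its angle weights the
    # opposite edge (i, j).
    for k in range(3):
        i = f[:, (k + 1) % 3]
        j = f[:, (k + 2) % 3]
        a = v[i] - v[f[:, k]]
        b = v[j] - v[f[:, k]]
        cot = (a * b).sum(axis=1) / (2.0 * areas)  # dot / |cross|
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    stiffness = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    stiffness.sum_duplicates()
    return stiffness, mass


def vertex_adjacency(mesh: TriangleMesh, weighted: bool = True) -> sparse.csr_matrix:
    """Symmetric vertex adjacency; weights are Euclidean edge lengths."""
    e = mesh.edges()
    w = mesh.edge_lengths() if weighted else np.ones(len(e))
    n = mesh.n_vertices
    adj = sparse.csr_matrix(
        (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n),
    )
    return adj


def geodesic_distances(mesh: TriangleMesh, seeds: Sequence[int]) -> GeodesicField:
    """Edge-graph geodesic distance (mm) from the nearest seed vertex.

    Disconnected vertices receive ``inf`` and are flagged on the result.
    """
    seeds = np.atleast_1d(np.asarray(seeds, dtype=np.int64))
    if seeds.size == 0:
        raise ValueError("seed set is empty")
    if seeds.min() < 0 or seeds.max() >= mesh.n_vertices:
        raise ValueError("seed index out of range")
    adj = vertex_adjacency(mesh)
    d = dijkstra(adj, directed=False, indices=seeds, min_only=True)
    return GeodesicField(distances=d, seed_indices=seeds,
                         has_unreachable=bool(np.isinf(d).any()))


def geodesic_matrix(mesh: TriangleMesh) -> np.ndarray:
    """All-pairs edge-graph geodesic distances, (n, n)."""
    adj = vertex_adjacency(mesh)
    return dijkstra(adj, directed=False)


def build_submesh(mesh: TriangleMesh, mask: Sequence[int],
                  mask_name: str = ""):
    """Cut the faces fully inside ``mask`` out of ``mesh`` and compact indices.

    Returns ``(submesh, selection)`` where ``selection.parent_indices`` maps
    each submesh vertex back to the parent.  Vertices of the mask that end up
    unreferenced by any kept face are dropped (the submesh is compact).
    """
    mask = np.unique(np.asarray(mask, dtype=np.int64))
    if mask.size == 0:
        raise ValueError("mask is empty")
    if mask.min() < 0 or mask.max() >= mesh.n_vertices:
        raise ValueError("mask index out of range")
    inside = np.zeros(mesh.n_vertices, dtype=bool)
    inside[mask] = True
    keep = inside[mesh.faces].all(axis=1)
    if not keep.any():
        raise ValueError("mask yields zero complete faces")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriangleMesh(
        vertices=mesh.vertices[used],
        faces=remap[faces],
        hemisphere=None if mesh.hemisphere is None else mesh.hemisphere[used],
    )
    return sub, SubsurfaceSelection(parent_indices=used, mask_name=mask_name)


def connected_hemispheres_ok(mesh: TriangleMesh) -> bool:
    """True when the edge graph is connected within each hemisphere label."""
    adj = vertex_adjacency(mesh, weighted=False)
    if mesh.hemisphere is None:
        return connected_components(adj, directed=False)[0] == 1
    for h in np.unique(mesh.hemisphere):
        idx = np.flatnonzero(mesh.hemisphere == h)
        ncomp = connected_components(adj[np.ix_(idx, idx)], directed=False)[0]
        if ncomp != 1:
            return False
    return True
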