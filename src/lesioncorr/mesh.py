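"""Geometry kernel: triangle/vertex areas, adjacency, graph shortest paths.

Areas feed the regional volumetrics (region volume = mean thickness x
surface area); shortest paths on the mesh edge graph reproduce the
anchor-to-anchor outlining used when a rater traces a lesion on the surface.
Paths are graph geodesics (along mesh edges), not exact polyhedral
geodesics, matching the interactive outlining behaviour.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .io_fs import SurfaceMesh, VertexScalarField

__all__ = [
    "AdjacencyGraph",
    "triangle_areas",
    "vertex_areas",
    "shortest_path",
    "path_length",
]

logger = logging.getLogger(__name__)


def triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face area in mm^2: half the cross-product magnitude of two edges.

    Degenerate (collinear) faces yield area 0 and a logged warning.
    """
    v = mesh.vertex_coords
    f = mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    if f.shape[0] and np.any(areas == 0.0):
        n_degen = int(np.sum(areas == 0.0))
        logger.warning("%d degenerate (zero-area) face(s) in mesh", n_degen)
    return areas


def vertex_areas(mesh: SurfaceMesh) -> VertexScalarField:
    """Per-vertex area: one third of the summed areas of incident faces.

    The uniform 1/3 split conserves total area exactly: the sum of vertex
    areas equals the sum of triangle areas. Vertices with no incident face
    get area 0.
    """
    tri = triangle_areas(mesh)
    va = np.zeros(mesh.n_vertices, dtype=np.float64)
    third = tri / 3.0
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], third)
    return VertexScalarField(va, units="mm2")


@dataclass
class AdjacencyGraph:
    """Symmetric vertex adjacency of a mesh with Euclidean edge lengths (mm)."""

    n_vertices: int
    indptr: np.ndarray  # CSR-style offsets into neighbors/lengths
    neighbors: np.ndarray  # sorted within each vertex's slice
    lengths: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: SurfaceMesh) -> "AdjacencyGraph":
        f = mesh.faces
        edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        both = np.vstack([edges, edges[:, ::-1]])
        order = np.lexsort((both[:, 1], both[:, 0]))
        both = both[order]
        lengths = np.linalg.norm(
            mesh.vertex_coords[both[:, 0]] - mesh.vertex_coords[both[:, 1]], axis=1
        )
        counts = np.bincount(both[:, 0], minlength=mesh.n_vertices)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        return cls(mesh.n_vertices, indptr.astype(np.int64), both[:, 1].astype(np.int64), lengths)

    def nbrs(self, v: int) -> np.ndarray:
        return self.neighbors[self.indptr[v] : self.indptr[v + 1]]

    def edge_lengths_of(self, v: int) -> np.ndarray:
        return self.lengths[self.indptr[v] : self.indptr[v + 1]]

    def are_adjacent(self, u: int, v: int) -> bool:
        return bool(np.isin(v, self.nbrs(u)).item())

    def component_labels(self) -> np.ndarray:
        """Connected-component id per vertex (BFS, ids in discovery order)."""
        comp = np.full(self.n_vertices, -1, dtype=np.int64)
        cid = 0
        for start in range(self.n_vertices):
            if comp[start] != -1:
                continue
            stack = [start]
            comp[start] = cid
            while stack:
                u = stack.pop()
                for w in self.nbrs(u):
                    if comp[w] == -1:
                        comp[w] = cid
                        stack.append(int(w))
            cid += 1
        return comp


def shortest_path(graph: AdjacencyGraph, src: int, dst: int) -> list[int]:
    """Minimum-length vertex path from ``src`` to ``dst`` along mesh edges.

    Dijkstra's algorithm with deterministic tie-breaking: among equal-length
    alternatives the predecessor with the lowest vertex index is kept, so the
    returned path is reproducible across runs and platforms.
    """
    n = graph.n_vertices
    for name, v in (("src", src), ("dst", dst)):
        if not (0 <= v < n):
            raise ValueError(f"{name} vertex {v} out of range [0, {n})")
    if src == dst:
        return [src]
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    dist[src] = 0.0
    heap: list[tuple[float, int]] = [(0.0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == dst:
            break
        for w, ell in zip(graph.nbrs(u), graph.edge_lengths_of(u)):
            if done[w]:
                continue
            nd = d + ell
            if nd < dist[w] or (nd == dist[w] and u < pred[w]):
                dist[w] = nd
                pred[w] = u
                heapq.heappush(heap, (nd, int(w)))
    if not done[dst]:
        comp = graph.component_labels()
        raise ValueError(
            f"vertices {src} and {dst} are disconnected "
            f"(components {int(comp[src])} and {int(comp[dst])})"
        )
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def path_length(graph: AdjacencyGraph, path: list[int]) -> float:
    """Summed edge length (mm) along a vertex path."""
    total = 0.0
    for u, v in zip(path[:-1], path[1:]):
        sl = slice(graph.indptr[u], graph.indptr[u + 1])
        idx = np.searchsorted(graph.neighbors[sl], v)
        nbrs = graph.neighbors[sl]
        if idx >= nbrs.size or nbrs[idx] != v:
            raise ValueError(f"path step {u}->{v} is not a mesh edge")
        total += float(graph.lengths[sl][idx])
    return total
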