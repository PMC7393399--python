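"""Independent brute-force reimplementations used as test oracles.

These deliberately avoid the package's vectorized code paths: plain Python
loops, plain BFS, and scipy's Dijkstra, so that agreement is evidence and
not tautology.
"""

import math
from collections import deque

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _scipy_dijkstra


def brute_vertex_areas(mesh):
    """1/3-of-incident-triangle vertex areas by an explicit face loop."""
    va = [0.0] * mesh.n_vertices
    for (a, b, c) in mesh.faces:
        pa, pb, pc = mesh.vertex_coords[a], mesh.vertex_coords[b], mesh.vertex_coords[c]
        area = 0.5 * float(np.linalg.norm(np.cross(pb - pa, pc - pa)))
        for i in (a, b, c):
            va[i] += area / 3.0
    return np.array(va)


def brute_region_stats(mesh, thickness, parc, exclude_ids=(), area_weighted=True):
    """Per-region stats by direct loops; returns dict region_name -> dict."""
    va = brute_vertex_areas(mesh)
    excl = set(int(i) for i in exclude_ids)
    out = {}
    for rid in sorted(set(parc.region_table) - {0}):
        vids = [
            v
            for v in range(mesh.n_vertices)
            if parc.region_id_per_vertex[v] == rid and v not in excl
        ]
        name = parc.region_table[rid][0]
        if not vids:
            out[name] = dict(num_vertices=0, area=0.0, mean_th=math.nan, volume=0.0)
            continue
        area = sum(va[v] for v in vids)
        w = [va[v] if area_weighted else 1.0 for v in vids]
        wsum = sum(w)
        mean_th = sum(wi * thickness[v] for wi, v in zip(w, vids)) / wsum
        out[name] = dict(
            num_vertices=len(vids),
            area=area,
            mean_th=mean_th,
            volume=area * mean_th / 1000.0,
        )
    return out


def adjacency_dict(mesh):
    adj = {v: set() for v in range(mesh.n_vertices)}
    for (a, b, c) in mesh.faces:
        for u, v in ((a, b), (b, c), (c, a)):
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
    return adj


def bfs_fill(mesh, boundary_set, seed):
    """Vertices reachable from seed without crossing the boundary, plus boundary."""
    adj = adjacency_dict(mesh)
    seen = {seed}
    q = deque([seed])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in seen and w not in boundary_set:
                seen.add(w)
                q.append(w)
    return seen | set(boundary_set)


def scipy_shortest_length(mesh, src, dst):
    """Graph-geodesic distance via scipy's Dijkstra."""
    f = mesh.faces
    edges = np.unique(np.sort(np.vstack([f[:, :2], f[:, 1:], f[:, ::2]]), axis=1), axis=0)
    w = np.linalg.norm(mesh.vertex_coords[edges[:, 0]] - mesh.vertex_coords[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n))
    return float(_scipy_dijkstra(g.tocsr(), indices=[src])[0, dst])


def count_map(overlays, n_vertices):
    counts = [0] * n_vertices
    for lab in overlays:
        for v in lab.vertex_ids:
            counts[int(v)] += 1
    return np.array(counts, dtype=float)
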