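"""Non-interactive reimplementation of the "Custom Fill" lesion-labeling
workflow: connect anchor points into a closed path on the mesh, flood-fill
the enclosed patch, save protocol-named lesion labels, and combine labels
into the per-hemisphere overlay used as an exclusion mask.

Boundary vertices are INCLUDED in the lesion label: the drawn outline passes
through inaccurate surface, so it is excluded from statistics too. Users who
want the open interior can subtract the boundary.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_fs import SurfaceLabel, SurfaceMesh, write_label
from .mesh import AdjacencyGraph, shortest_path

__all__ = [
    "ClosedPath",
    "close_path",
    "flood_fill",
    "save_lesion_label",
    "combine_labels",
    "DEFAULT_MAX_FILL_FRACTION",
]

logger = logging.getLogger(__name__)

#: Fills claiming more than this fraction of the hemisphere's vertices are
#: rejected as escaped (the outline was not closed).
DEFAULT_MAX_FILL_FRACTION = 0.5


@dataclass
class ClosedPath:
    """An ordered cycle of mutually adjacent vertices (first = last implicitly)."""

    vertices: np.ndarray  # (K,) int64, closure implicit
    hemisphere: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64).ravel()
        if self.vertices.size < 3:
            raise ValueError(f"closed path needs >= 3 vertices, got {self.vertices.size}")
        if np.unique(self.vertices).size != self.vertices.size:
            raise ValueError("closed path repeats a vertex")

    def __len__(self) -> int:
        return self.vertices.size

    def vertex_set(self) -> set[int]:
        return set(self.vertices.tolist())


def close_path(
    mesh: SurfaceMesh,
    anchors: list[int],
    hemisphere: str = "lh",
    graph: AdjacencyGraph | None = None,
) -> ClosedPath:
    """Connect ordered anchor points into a closed path through mesh edges.

    Consecutive anchors (and last back to first) are joined by the shortest
    edge path; junction vertices shared by consecutive segments appear once.
    The rater's outline must not self-intersect: a vertex reached by two
    different segments is an error.
    """
    anchors = [int(a) for a in anchors]
    if len(anchors) < 3:
        raise ValueError(
            f"need >= 3 anchor points to outline a lesion (an unbroken chain), got {len(anchors)}"
        )
    if len(set(anchors)) != len(anchors):
        raise ValueError("anchor list repeats a vertex")
    for a in anchors:
        if not (0 <= a < mesh.n_vertices):
            raise ValueError(f"anchor vertex {a} out of mesh range [0, {mesh.n_vertices})")
    if graph is None:
        graph = AdjacencyGraph.from_mesh(mesh)
    cycle: list[int] = []
    for a, b in zip(anchors, anchors[1:] + anchors[:1]):
        seg = shortest_path(graph, a, b)
        cycle.extend(seg[:-1])  # drop junction; next segment starts with it
    arr = np.asarray(cycle, dtype=np.int64)
    if np.unique(arr).size != arr.size:
        raise ValueError("outline self-intersects: a vertex occurs in two path segments")
    return ClosedPath(arr, hemisphere)


def flood_fill(
    mesh: SurfaceMesh,
    boundary: ClosedPath,
    seed: int,
    max_fill_fraction: float = DEFAULT_MAX_FILL_FRACTION,
    graph: AdjacencyGraph | None = None,
) -> SurfaceLabel:
    """Fill the patch enclosed by ``boundary`` starting from ``seed``.

    The label is the boundary plus every vertex reachable from the seed
    without traversing a boundary vertex (breadth-first on the mesh graph).
    A fill that claims more than ``max_fill_fraction`` of the hemisphere's
    vertices signals an unclosed outline and raises.
    """
    seed = int(seed)
    if not (0 <= seed < mesh.n_vertices):
        raise ValueError(f"seed vertex {seed} out of mesh range [0, {mesh.n_vertices})")
    bset = boundary.vertex_set()
    if seed in bset:
        raise ValueError(f"seed {seed} lies on path")
    if graph is None:
        graph = AdjacencyGraph.from_mesh(mesh)
    limit = max_fill_fraction * mesh.n_vertices
    visited = np.zeros(mesh.n_vertices, dtype=bool)
    visited[seed] = True
    queue: deque[int] = deque([seed])
    n_filled = 1
    while queue:
        u = queue.popleft()
        for w in graph.nbrs(u):
            w = int(w)
            if visited[w] or w in bset:
                continue
            visited[w] = True
            n_filled += 1
            if n_filled > limit:
                raise ValueError(
                    f"fill escaped outline: {n_filled} vertices exceed "
                    f"max_fill_fraction={max_fill_fraction} of {mesh.n_vertices} "
                    "(is the path closed?)"
                )
            queue.append(w)
    ids = np.union1d(np.flatnonzero(visited), np.asarray(sorted(bset), dtype=np.int64))
    return SurfaceLabel(
        name=f"{boundary.hemisphere}.lesion",
        hemisphere=boundary.hemisphere,
        vertex_ids=ids,
    )


def save_lesion_label(
    label: SurfaceLabel,
    mesh: SurfaceMesh,
    subject_dir: str | Path,
    ordinal: int,
    overwrite: bool = False,
) -> Path:
    """Write ``<hemi>.lesion-<NN>.label`` under ``subject_dir/label/``.

    ``NN`` is the zero-padded ordinal (1..99) counting that hemisphere's
    lesions for the subject.
    """
    if not (1 <= ordinal <= 99):
        raise ValueError(f"lesion ordinal must be in [1, 99], got {ordinal}")
    label_dir = Path(subject_dir) / "label"
    label_dir.mkdir(parents=True, exist_ok=True)
    path = label_dir / f"{label.hemisphere}.lesion-{ordinal:02d}.label"
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    named = SurfaceLabel(
        name=f"{label.hemisphere}.lesion-{ordinal:02d}",
        hemisphere=label.hemisphere,
        vertex_ids=label.vertex_ids,
        per_vertex_value=label.per_vertex_value,
    )
    write_label(named, mesh, path)
    logger.info("wrote lesion label %s (%d vertices)", path, len(named))
    return path


def combine_labels(labels: list[SurfaceLabel], hemisphere: str) -> SurfaceLabel:
    """Union of lesion labels on one hemisphere: the ``<hemi>.all-lesions`` overlay.

    The protocol places every label on a single hemisphere; a label from the
    other hemisphere is an error.
    """
    for lab in labels:
        if lab.hemisphere != hemisphere:
            raise ValueError(
                f"label {lab.name!r} is on hemisphere {lab.hemisphere!r}, "
                f"not {hemisphere!r}: labels must only be placed on a single hemisphere"
            )
    if labels:
        ids = np.unique(np.concatenate([lab.vertex_ids for lab in labels]))
    else:
        ids = np.empty(0, dtype=np.int64)
    return SurfaceLabel(name=f"{hemisphere}.all-lesions", hemisphere=hemisphere, vertex_ids=ids)
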