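"""Synthetic cortical subjects and voxel phantoms with known ground truth.

Real inputs to the lesion-correction workflow (reconstructed surfaces,
thickness overlays, a 7-network parcellation, manually drawn lesion labels,
and segmented T1 volumes) come from an MRI pipeline and cannot be shipped.
This module emulates each of them on analytic geometry:

* spheres (optionally "wrinkled" by a radial perturbation) stand in for
  cortical hemispheres — the regional statistics are geometry-agnostic and
  spheres admit closed-form area checks;
* a seeded nearest-centroid parcellation yields 7 contiguous patches named
  after the canonical 7-network resting-state atlas;
* a smooth thickness field (base 2.5 mm + low-frequency perturbation) is
  locally thinned inside lesions, mimicking encephalomalacic tissue loss;
* lesions grow breadth-first from a random in-network seed until a target
  vertex-area fraction of the network is first reached, so the achieved
  fraction is known to within one vertex area (the quantization bound);
* voxel phantoms lay out concentric WM/GM/CSF shells with Gaussian
  intensities, plus an optional ellipsoidal lesion mask;
* rater matrices add per-rater Gaussian error to true lesion volumes, with
  the theoretical ICC recorded.

Everything is driven by one integer seed through named per-component
generators, so identical seeds give byte-identical subject directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_fs import (
    Parcellation,
    RegionStatsRow,
    SurfaceLabel,
    SurfaceMesh,
    VertexScalarField,
    VoxelVolume,
    write_annot,
    write_curv,
    write_label,
    write_surface,
)
from .mesh import AdjacencyGraph, vertex_areas
from .qc import RaterMatrix, TissueMasks

__all__ = [
    "NETWORK_NAMES",
    "SyntheticSubject",
    "make_icosphere",
    "make_subject",
    "make_phantom",
    "make_rater_data",
    "write_subject_dir",
]

#: Canonical 7-network atlas names, region ids 1..7 (0 = unknown).
NETWORK_NAMES = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "Salience",
    "Limbic",
    "ExecutiveControl",
    "DefaultMode",
)

#: Deterministic distinct colors (region id -> RGB); id 0 is "unknown".
_NETWORK_COLORS = {
    0: (25, 5, 25),
    1: (120, 18, 134),
    2: (70, 130, 180),
    3: (0, 118, 14),
    4: (196, 58, 250),
    5: (220, 248, 164),
    6: (230, 148, 34),
    7: (205, 62, 78),
}

_BASE_THICKNESS_MM = 2.5
_HEMI_RADIUS_MM = 50.0  # sphere of ~314 cm^2, the order of one hemisphere's area


def make_icosphere(subdivisions: int, radius: float = 1.0) -> SurfaceMesh:
    """Subdivided icosahedron projected to a sphere of the given radius.

    Yields ``10 * 4**subdivisions + 2`` vertices; construction order is
    deterministic.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in (verts / np.linalg.norm(verts, axis=1, keepdims=True))]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in cache:
                m = np.asarray(verts[a]) + np.asarray(verts[b])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    coords = np.asarray(verts, dtype=np.float64) * radius
    return SurfaceMesh(coords, np.asarray(faces, dtype=np.int32))


def _wrinkle(mesh: SurfaceMesh, amplitude: float, rng: np.random.Generator) -> SurfaceMesh:
    """Radial sinusoidal perturbation that de-trivializes vertex areas."""
    v = mesh.vertex_coords
    r = np.linalg.norm(v, axis=1, keepdims=True)
    unit = v / r
    phase = rng.uniform(0, 2 * np.pi, size=3)
    bump = (
        np.sin(3 * np.arccos(np.clip(unit[:, 2], -1, 1)) + phase[0])
        * np.cos(4 * np.arctan2(unit[:, 1], unit[:, 0]) + phase[1])
    )
    scale = 1.0 + amplitude * bump[:, None]
    return SurfaceMesh(unit * r * scale, mesh.faces)


@dataclass
class SyntheticSubject:
    """A complete synthetic subject with recoverable ground truth."""

    meshes: dict[str, SurfaceMesh]
    thickness: dict[str, VertexScalarField]
    parcellations: dict[str, Parcellation]
    lesions: dict[str, list[SurfaceLabel]]
    ground_truth: dict
    seed: int
    params: dict = field(default_factory=dict)


def _grow_parcellation(
    mesh: SurfaceMesh, n_networks: int, rng: np.random.Generator
) -> Parcellation:
    """Nearest-centroid parcellation: contiguous patches on the sphere."""
    unit = mesh.vertex_coords / np.linalg.norm(mesh.vertex_coords, axis=1, keepdims=True)
    centroids = rng.normal(size=(n_networks, 3))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    ids = np.argmax(unit @ centroids.T, axis=1).astype(np.int32) + 1
    table = {0: ("Unknown", _NETWORK_COLORS[0])}
    for i in range(n_networks):
        name = NETWORK_NAMES[i] if i < len(NETWORK_NAMES) else f"Network{i + 1}"
        table[i + 1] = (name, _NETWORK_COLORS.get(i + 1, (10 + 7 * i, 40 + 11 * i, 90 + 13 * i)))
    return Parcellation(ids, table)


def _smooth_thickness(mesh: SurfaceMesh, rng: np.random.Generator) -> np.ndarray:
    """Base 2.5 mm plus a low-frequency spatial perturbation, floored at 0.1 mm."""
    v = mesh.vertex_coords
    r = np.linalg.norm(v, axis=1).mean()
    th = np.full(mesh.n_vertices, _BASE_THICKNESS_MM)
    for _ in range(3):
        k = rng.normal(size=3) * (2.0 / r)
        th += 0.15 * np.sin(v @ k + rng.uniform(0, 2 * np.pi))
    return np.maximum(th, 0.1)


def _grow_lesion(
    graph: AdjacencyGraph,
    va: np.ndarray,
    network_mask: np.ndarray,
    target_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Breadth-first lesion growth inside one network by accumulated vertex area.

    Vertices join ring by ring (within a ring, lowest index first) until the
    accumulated area fraction of the network first reaches the target.
    Returns (vertex ids, achieved fraction).
    """
    members = np.flatnonzero(network_mask)
    total = float(va[members].sum())
    seed = int(rng.choice(members))
    in_lesion = np.zeros(va.size, dtype=bool)
    in_lesion[seed] = True
    acc = float(va[seed])
    frontier = [seed]
    while acc < target_fraction * total:
        ring: set[int] = set()
        for u in frontier:
            for w in graph.nbrs(u):
                w = int(w)
                if network_mask[w] and not in_lesion[w]:
                    ring.add(w)
        if not ring:
            raise ValueError(
                f"unreachable target fraction {target_fraction}: network component "
                f"exhausted at fraction {acc / total:.4f}"
            )
        for w in sorted(ring):
            in_lesion[w] = True
            acc += float(va[w])
            if acc >= target_fraction * total:
                break
        frontier = sorted(ring & set(np.flatnonzero(in_lesion).tolist()))
    return np.flatnonzero(in_lesion), acc / total


def _oracle_region_stats(
    mesh: SurfaceMesh,
    thickness: np.ndarray,
    parc: Parcellation,
    exclude: set[int],
    hemisphere: str,
) -> list[RegionStatsRow]:
    """Plain-loop per-vertex/per-triangle statistics used for ground truth.

    Deliberately independent of :mod:`lesioncorr.regionstats`: it loops over
    triangles to attribute one third of each area to its corners, then over
    vertices to accumulate the regional sums.
    """
    import math

    va = [0.0] * mesh.n_vertices
    for (a, b, c) in mesh.faces:
        pa, pb, pc = (mesh.vertex_coords[i] for i in (a, b, c))
        area = 0.5 * float(np.linalg.norm(np.cross(pb - pa, pc - pa)))
        for i in (a, b, c):
            va[i] += area / 3.0
    rows = []
    for rid in parc.region_ids():
        vids = [
            v
            for v in range(mesh.n_vertices)
            if parc.region_id_per_vertex[v] == rid and v not in exclude
        ]
        name = parc.name_of(rid)
        if not vids:
            rows.append(RegionStatsRow(name, hemisphere, 0, 0.0, math.nan, math.nan, 0.0, False))
            continue
        area = sum(va[v] for v in vids)
        mean_th = sum(va[v] * thickness[v] for v in vids) / area
        var_th = sum(va[v] * (thickness[v] - mean_th) ** 2 for v in vids) / area
        rows.append(
            RegionStatsRow(
                name, hemisphere, len(vids), area, mean_th,
                math.sqrt(max(var_th, 0.0)), area * mean_th / 1000.0,
            )
        )
    return rows


def make_subject(
    seed: int,
    subdivisions: int = 4,
    n_networks: int = 7,
    lesion_specs: Sequence[tuple] = (("Limbic", 0.10), ("DefaultMode", 0.05)),
    thinning: float = 0.2,
    radius_mm: float = _HEMI_RADIUS_MM,
    wrinkle_amplitude: float = 0.03,
    hemispheres: Sequence[str] = ("lh", "rh"),
) -> SyntheticSubject:
    """Generate a synthetic subject with planted lesions of known area fraction.

    ``lesion_specs`` lists ``(network, target_area_fraction)`` or
    ``(network, target_area_fraction, hemisphere)`` tuples (hemisphere
    defaults to ``"lh"``); ``thinning`` multiplies the thickness inside each
    lesion, emulating encephalomalacic thinning. Ground truth records the
    achieved (vertex-quantized) fraction, its quantization bound, and exact
    pre/post regional statistics computed by an independent plain-loop
    oracle.
    """
    specs = []
    for s in lesion_specs:
        net, frac = s[0], float(s[1])
        hemi = s[2] if len(s) > 2 else "lh"
        if not (0.0 < frac < 1.0):
            raise ValueError(f"target area fraction must be in (0, 1), got {frac}")
        if hemi not in hemispheres:
            raise ValueError(f"lesion hemisphere {hemi!r} not among {tuple(hemispheres)}")
        specs.append((net, frac, hemi))

    meshes: dict[str, SurfaceMesh] = {}
    thickness: dict[str, VertexScalarField] = {}
    parcs: dict[str, Parcellation] = {}
    lesions: dict[str, list[SurfaceLabel]] = {h: [] for h in hemispheres}
    gt_lesions = []
    gt_stats = {}

    for hemi in hemispheres:
        hseed = seed * 10 + (0 if hemi == "lh" else 1)
        mesh = make_icosphere(subdivisions, radius_mm)
        if wrinkle_amplitude:
            mesh = _wrinkle(mesh, wrinkle_amplitude, np.random.default_rng(hseed * 7 + 1))
        parc = _grow_parcellation(mesh, n_networks, np.random.default_rng(hseed * 7 + 2))
        th = _smooth_thickness(mesh, np.random.default_rng(hseed * 7 + 3))
        graph = AdjacencyGraph.from_mesh(mesh)
        va = vertex_areas(mesh).values
        name_to_id = {name: rid for rid, (name, _c) in parc.region_table.items()}

        ordinal = 0
        for net, frac, hemi_spec in specs:
            if hemi_spec != hemi:
                continue
            rid = name_to_id.get(net) if isinstance(net, str) else int(net)
            if rid is None or rid not in parc.region_table or rid == 0:
                raise ValueError(f"unknown network {net!r}")
            mask = parc.region_id_per_vertex == rid
            lrng = np.random.default_rng(hseed * 7 + 4 + ordinal)
            ids, achieved = _grow_lesion(graph, va, mask, frac, lrng)
            ordinal += 1
            lab = SurfaceLabel(
                name=f"{hemi}.lesion-{ordinal:02d}", hemisphere=hemi, vertex_ids=ids
            )
            lesions[hemi].append(lab)
            th[ids] *= thinning
            net_area = float(va[mask].sum())
            gt_lesions.append(
                {
                    "hemisphere": hemi,
                    "network": parc.name_of(rid),
                    "label_name": lab.name,
                    "target_fraction": frac,
                    "achieved_fraction": achieved,
                    "quantization_bound": float(va[mask].max()) / net_area,
                    "n_vertices": int(ids.size),
                }
            )

        meshes[hemi] = mesh
        parcs[hemi] = parc
        thickness[hemi] = VertexScalarField(th, units="mm")
        excl = set()
        for lab in lesions[hemi]:
            excl.update(int(v) for v in lab.vertex_ids)
        gt_stats[hemi] = {
            "pre": _oracle_region_stats(mesh, th, parc, set(), hemi),
            "post": _oracle_region_stats(mesh, th, parc, excl, hemi),
        }

    params = {
        "subdivisions": subdivisions,
        "n_networks": n_networks,
        "thinning": thinning,
        "radius_mm": radius_mm,
        "wrinkle_amplitude": wrinkle_amplitude,
    }
    return SyntheticSubject(
        meshes=meshes,
        thickness=thickness,
        parcellations=parcs,
        lesions=lesions,
        ground_truth={"lesions": gt_lesions, "stats": gt_stats},
        seed=seed,
        params=params,
    )


def write_subject_dir(subject: SyntheticSubject, root: str | Path) -> Path:
    """Write a FreeSurfer-style subject directory (surf/, label/, parc/).

    The emitted files fully determine the subject; identical seeds give
    byte-identical directories.
    """
    root = Path(root)
    (root / "surf").mkdir(parents=True, exist_ok=True)
    (root / "label").mkdir(exist_ok=True)
    (root / "parc").mkdir(exist_ok=True)
    for hemi, mesh in subject.meshes.items():
        write_surface(mesh, root / "surf" / f"{hemi}.pial")
        write_curv(subject.thickness[hemi], root / "surf" / f"{hemi}.thickness", fnum=mesh.n_faces)
        write_annot(subject.parcellations[hemi], root / "parc" / f"{hemi}.networks.annot")
        for lab in subject.lesions[hemi]:
            write_label(lab, mesh, root / "label" / f"{lab.name}.label")
    return root


def make_phantom(
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 64),
    tissue_params: dict[str, tuple[float, float]] | None = None,
    lesion_ellipsoid: tuple[float, float, float] | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[VoxelVolume, TissueMasks, np.ndarray | None]:
    """Concentric-shell WM/GM/CSF phantom with Gaussian class intensities.

    WM fills a central ball, GM and CSF the two shells around it (radii at
    25/35/45% of the smallest grid dimension). ``tissue_params`` maps class
    name to (mean, SD); defaults are (150, 10), (100, 10), (50, 10) —
    T1-like contrast ordering. ``lesion_ellipsoid`` gives full axis lengths
    in mm of a centered ellipsoidal lesion mask (or None).
    """
    if any(s < 8 for s in shape):
        raise ValueError(f"degenerate phantom shape {shape}")
    params = {"wm": (150.0, 10.0), "gm": (100.0, 10.0), "csf": (50.0, 10.0)}
    if tissue_params:
        params.update({k: (float(m), float(s)) for k, (m, s) in tissue_params.items()})
    for cls, (_m, s) in params.items():
        if s <= 0:
            raise ValueError(f"{cls} intensity SD must be > 0")
    rng = np.random.default_rng(seed)
    dx, dy, dz = voxel_size
    grids = np.meshgrid(
        (np.arange(shape[0]) - (shape[0] - 1) / 2) * dx,
        (np.arange(shape[1]) - (shape[1] - 1) / 2) * dy,
        (np.arange(shape[2]) - (shape[2] - 1) / 2) * dz,
        indexing="ij",
    )
    r = np.sqrt(sum(g**2 for g in grids))
    m = min(shape[i] * voxel_size[i] for i in range(3))
    wm = r < 0.25 * m
    gm = (r >= 0.25 * m) & (r < 0.35 * m)
    csf = (r >= 0.35 * m) & (r < 0.45 * m)
    intensities = np.zeros(shape, dtype=np.float64)
    for mask, cls in ((wm, "wm"), (gm, "gm"), (csf, "csf")):
        mu, sd = params[cls]
        intensities[mask] = rng.normal(mu, sd, size=int(mask.sum()))
    lesion = None
    if lesion_ellipsoid is not None:
        a, b, c = (float(x) / 2.0 for x in lesion_ellipsoid)  # semi-axes, mm
        lesion = (grids[0] / a) ** 2 + (grids[1] / b) ** 2 + (grids[2] / c) ** 2 <= 1.0
    vol = VoxelVolume(intensities, voxel_size)
    return vol, TissueMasks(wm, gm, csf), lesion


def make_rater_data(
    seed: int,
    n_subjects: int = 20,
    true_volume_mean_ml: float = 15.0,
    true_volume_sd_ml: float = 3.0,
    rater_sds: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[RaterMatrix, dict]:
    """Simulated lesion-volume ratings: true volume + per-rater Gaussian error.

    Defaults emulate a reliability set of 20 scans read by 3 raters. The
    returned info dict records the theoretical agreement ICC,
    ``var_true / (var_true + mean rater variance)``.
    """
    if n_subjects < 2 or len(rater_sds) < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    rng = np.random.default_rng(seed)
    true = rng.normal(true_volume_mean_ml, true_volume_sd_ml, size=n_subjects)
    cols = [true + rng.normal(0.0, sd, size=n_subjects) if sd > 0 else true.copy() for sd in rater_sds]
    var_true = true_volume_sd_ml**2
    mean_rater_var = float(np.mean([sd**2 for sd in rater_sds]))
    info = {
        "theoretical_icc": var_true / (var_true + mean_rater_var),
        "var_true": var_true,
        "mean_rater_variance": mean_rater_var,
    }
    return RaterMatrix(np.column_stack(cols)), info
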