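"""Regional cortical statistics with lesion exclusion.

The volumetric model is the classic surface-based one: a region's volume is
its mean cortical thickness times its surface area. Surface area is
accumulated from per-vertex areas (one third of each incident triangle), the
mean thickness is area-weighted by default, and

    volume_ml = surface_area_mm2 * mean_thickness_mm / 1000.

Lesion correction removes the vertices of a lesion overlay from every
region before the sums are taken, yielding "post-correction" statistics,
and the module quantifies how lesions overlap a network parcellation:
percent of each network's surface area affected, percent volume change,
lesion counts per network, networks per lesion, and group-level lesion
frequency maps on a shared template mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_fs import (
    Parcellation,
    RegionStatsRow,
    SurfaceLabel,
    SurfaceMesh,
    VertexScalarField,
)
from .mesh import vertex_areas

__all__ = [
    "NetworkOverlapRow",
    "region_stats",
    "corrected_stats",
    "pct_surface_area_affected",
    "pct_volume_change",
    "lesions_per_network",
    "networks_per_lesion",
    "group_frequency_map",
    "network_overlap_report",
]


@dataclass
class NetworkOverlapRow:
    """Per-network lesion overlap summary (one subject)."""

    network_name: str
    n_lesions_in_network: int
    is_lesioned: bool
    pct_surface_area_affected: float
    pre_volume_ml: float
    post_volume_ml: float
    pct_volume_change: float


def _check_lengths(mesh: SurfaceMesh, thickness: VertexScalarField, parc: Parcellation) -> None:
    n = mesh.n_vertices
    if len(thickness) != n:
        raise ValueError(f"thickness has {len(thickness)} values but mesh has {n} vertices")
    if parc.n_vertices != n:
        raise ValueError(f"parcellation covers {parc.n_vertices} vertices but mesh has {n}")


def region_stats(
    mesh: SurfaceMesh,
    thickness: VertexScalarField,
    parc: Parcellation,
    exclude: SurfaceLabel | None = None,
    hemisphere: str = "lh",
    area_weighted: bool = True,
) -> list[RegionStatsRow]:
    """Per-region vertex count, surface area, thickness and volume.

    Vertices in ``exclude`` (and unassigned vertices, id 0) never contribute.
    ``area_weighted`` weights the thickness mean/SD by per-vertex area,
    consistent with the area-based volume formula; pass False for the plain
    per-vertex average. Regions emptied by exclusion are reported with zero
    vertices and undefined (NaN) thickness.
    """
    _check_lengths(mesh, thickness, parc)
    va = vertex_areas(mesh).values
    keep = np.ones(mesh.n_vertices, dtype=bool)
    if exclude is not None:
        keep &= ~exclude.indicator(mesh.n_vertices)
    rows = []
    for rid in parc.region_ids():
        member = (parc.region_id_per_vertex == rid) & keep
        nv = int(member.sum())
        name = parc.name_of(rid)
        if nv == 0:
            rows.append(
                RegionStatsRow(name, hemisphere, 0, 0.0, math.nan, math.nan, 0.0, False)
            )
            continue
        areas = va[member]
        th = thickness.values[member]
        total_area = float(areas.sum())
        w = areas if area_weighted else np.ones_like(areas)
        wsum = float(w.sum())
        if wsum > 0:
            mean_th = float(np.sum(w * th) / wsum)
            var_th = float(np.sum(w * (th - mean_th) ** 2) / wsum)
        else:  # all-degenerate patch: fall back to the unweighted average
            mean_th = float(th.mean())
            var_th = float(th.var())
        rows.append(
            RegionStatsRow(
                region_name=name,
                hemisphere=hemisphere,
                num_vertices=nv,
                surface_area_mm2=total_area,
                mean_thickness_mm=mean_th,
                thickness_sd_mm=math.sqrt(max(var_th, 0.0)),
                volume_ml=total_area * mean_th / 1000.0,
            )
        )
    return rows


def corrected_stats(
    mesh: SurfaceMesh,
    thickness: VertexScalarField,
    parc: Parcellation,
    overlay: SurfaceLabel,
    hemisphere: str = "lh",
    area_weighted: bool = True,
) -> tuple[list[RegionStatsRow], list[RegionStatsRow]]:
    """Pre- and post-correction statistics for one hemisphere.

    ``pre`` is :func:`region_stats` with no exclusion; ``post`` excludes the
    combined lesion overlay. Per region, pre area = post area + the area of
    the lesion-region intersection (conservation).
    """
    pre = region_stats(mesh, thickness, parc, None, hemisphere, area_weighted)
    post = region_stats(mesh, thickness, parc, overlay, hemisphere, area_weighted)
    return pre, post


def pct_surface_area_affected(
    mesh: SurfaceMesh,
    parc: Parcellation,
    lesions: list[SurfaceLabel],
) -> dict[str, float]:
    """Percent of each network's vertex area covered by the lesion union."""
    if parc.n_vertices != mesh.n_vertices:
        raise ValueError("parcellation/mesh vertex count mismatch")
    va = vertex_areas(mesh).values
    lesioned = np.zeros(mesh.n_vertices, dtype=bool)
    for lab in lesions:
        lesioned |= lab.indicator(mesh.n_vertices)
    out = {}
    for rid in parc.region_ids():
        member = parc.region_id_per_vertex == rid
        denom = float(va[member].sum())
        hit = float(va[member & lesioned].sum())
        out[parc.name_of(rid)] = 100.0 * hit / denom if denom > 0 else 0.0
    return out


def pct_volume_change(pre_volume: float, post_volume: float, denominator: str = "post") -> float:
    """Signed percent volume change, 100 * (post - pre) / denominator volume.

    ``denominator`` selects the pre- or post-correction volume as reference
    (default "post"); the reference volume must be positive.
    """
    if denominator not in ("pre", "post"):
        raise ValueError(f"denominator must be 'pre' or 'post', got {denominator!r}")
    denom = pre_volume if denominator == "pre" else post_volume
    if denom <= 0:
        raise ValueError(f"{denominator}-correction volume must be > 0, got {denom}")
    return 100.0 * (post_volume - pre_volume) / denom


def lesions_per_network(
    parc: Parcellation, lesions: list[SurfaceLabel]
) -> dict[str, tuple[int, bool]]:
    """Per network: number of distinct lesions overlapping it, and a lesioned flag.

    A lesion overlapping several networks is counted once in each, so the
    counts sum to more than the number of lesions.
    """
    ids = parc.region_id_per_vertex
    out = {}
    for rid in parc.region_ids():
        count = 0
        for lab in lesions:
            valid = lab.vertex_ids[lab.vertex_ids < ids.size]
            if np.any(ids[valid] == rid):
                count += 1
        out[parc.name_of(rid)] = (count, count >= 1)
    return out


def networks_per_lesion(parc: Parcellation, lesion: SurfaceLabel) -> int:
    """Number of distinct networks (nonzero regions) a lesion touches."""
    valid = lesion.vertex_ids[lesion.vertex_ids < parc.n_vertices]
    touched = np.unique(parc.region_id_per_vertex[valid])
    return int(np.sum(touched != 0))


def group_frequency_map(
    overlays_by_subject: list[SurfaceLabel], n_template_vertices: int
) -> VertexScalarField:
    """Vertex-wise lesion frequency across subjects on a common template mesh.

    The value at a vertex is the number of subjects whose overlay contains
    it (0..n_subjects). All overlays must be indexed on the same template.
    """
    counts = np.zeros(n_template_vertices, dtype=np.float64)
    for lab in overlays_by_subject:
        if len(lab) and lab.vertex_ids.max() >= n_template_vertices:
            raise ValueError(
                f"overlay {lab.name!r} references vertex {int(lab.vertex_ids.max())}, "
                f"outside the {n_template_vertices}-vertex template mesh"
            )
        counts[lab.vertex_ids] += 1
    return VertexScalarField(counts, units="count")


def network_overlap_report(
    mesh: SurfaceMesh,
    thickness: VertexScalarField,
    parc: Parcellation,
    lesions: list[SurfaceLabel],
    hemisphere: str = "lh",
    denominator: str = "post",
) -> list[NetworkOverlapRow]:
    """One row per network: lesion counts, % area affected, pre/post volume."""
    from .labeling import combine_labels

    overlay = combine_labels(lesions, hemisphere) if lesions else None
    pre = region_stats(mesh, thickness, parc, None, hemisphere)
    post = (
        region_stats(mesh, thickness, parc, overlay, hemisphere)
        if overlay is not None
        else pre
    )
    pct_area = pct_surface_area_affected(mesh, parc, lesions)
    counts = lesions_per_network(parc, lesions)
    rows = []
    for pr, po in zip(pre, post):
        n_les, flag = counts[pr.region_name]
        denom_vol = pr.volume_ml if denominator == "pre" else po.volume_ml
        pct_dv = (
            pct_volume_change(pr.volume_ml, po.volume_ml, denominator)
            if denom_vol > 0
            else math.nan
        )
        rows.append(
            NetworkOverlapRow(
                network_name=pr.region_name,
                n_lesions_in_network=n_les,
                is_lesioned=flag,
                pct_surface_area_affected=pct_area[pr.region_name],
                pre_volume_ml=pr.volume_ml,
                post_volume_ml=po.volume_ml,
                pct_volume_change=pct_dv,
            )
        )
    return rows


def overlap_report_frame(rows: list[NetworkOverlapRow], hemisphere: str) -> pd.DataFrame:
    """Tabular form of a network overlap report (adds a hemisphere column)."""
    return pd.DataFrame(
        [
            {
                "hemisphere": hemisphere,
                "network": r.network_name,
                "n_lesions_in_network": r.n_lesions_in_network,
                "is_lesioned": r.is_lesioned,
                "pct_surface_area_affected": r.pct_surface_area_affected,
                "pre_volume_ml": r.pre_volume_ml,
                "post_volume_ml": r.post_volume_ml,
                "pct_volume_change": r.pct_volume_change,
            }
            for r in rows
        ]
    )
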