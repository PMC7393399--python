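"""Readers and writers for the FreeSurfer file formats the lesion-correction
workflow touches, plus the domain containers they populate.

Four formats are implemented bit-exactly, all big-endian regardless of host
byte order:

* binary triangle surface (magic ``0xFFFFFE``): vertex coordinates + faces;
* binary per-vertex scalar ("curv", new format, magic ``0xFFFFFF``): one
  float per vertex, e.g. cortical thickness in mm;
* ASCII label: a named set of vertex indices on one hemisphere;
* binary annotation (+ embedded colortable, "new-style" version 2): a
  per-vertex region assignment such as a 7-network parcellation.

Vertex indices are 0-based everywhere, matching the on-disk label format.
A TSV writer for per-region statistics tables rounds out the module.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SurfaceMesh",
    "VertexScalarField",
    "SurfaceLabel",
    "Parcellation",
    "VoxelVolume",
    "RegionStatsRow",
    "read_surface",
    "write_surface",
    "read_curv",
    "write_curv",
    "read_label",
    "write_label",
    "parse_label_name",
    "read_annot",
    "write_annot",
    "write_stats_table",
    "read_stats_table",
]

TRIANGLE_MAGIC = 0xFFFFFE
CURV_MAGIC = 0xFFFFFF

_LABEL_NAME_RE = re.compile(r"^(lh|rh)\.([A-Za-z0-9_-]+)\.label$")
_LESION_STEM_RE = re.compile(r"^lesion-(\d{2})$")


class FormatError(ValueError):
    """A file does not conform to the expected FreeSurfer format."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated cortical sheet: vertex coordinates (mm) and faces.

    Faces are triples of 0-based vertex indices.
    """

    vertex_coords: np.ndarray  # (N, 3) float64
    faces: np.ndarray  # (M, 3) int32

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int32).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        n = self.n_vertices
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError(
                f"face vertex index out of range [0, {n}): "
                f"min {self.faces.min()}, max {self.faces.max()}"
            )
        if self.n_faces:
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("a face repeats a vertex")
            # each undirected edge shared by at most 2 faces
            edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            edges.sort(axis=1)
            _, counts = np.unique(edges, axis=0, return_counts=True)
            if counts.max(initial=0) > 2:
                raise ValueError("an edge is shared by more than 2 faces")


@dataclass
class VertexScalarField:
    """One scalar per mesh vertex (thickness in mm, curvature, counts)."""

    values: np.ndarray  # (N,) float64
    units: str = "dimensionless"  # mm | dimensionless | count

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SurfaceLabel:
    """A named set of vertex indices on one hemisphere.

    ``vertex_ids`` are kept sorted and unique; ``per_vertex_value`` (parallel
    to ``vertex_ids``) defaults to zeros, matching the on-disk label format.
    """

    name: str
    hemisphere: str  # "lh" | "rh"
    vertex_ids: np.ndarray  # (K,) int64, sorted unique
    per_vertex_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("lh", "rh"):
            raise ValueError(f"hemisphere must be 'lh' or 'rh', got {self.hemisphere!r}")
        ids = np.asarray(self.vertex_ids, dtype=np.int64).ravel()
        if ids.size and ids.min() < 0:
            raise ValueError("negative vertex index in label")
        order = np.argsort(ids, kind="stable")
        sorted_ids = ids[order]
        if np.any(np.diff(sorted_ids) == 0):
            raise FormatError("duplicate vertex index in label")
        self.vertex_ids = sorted_ids
        if self.per_vertex_value is None:
            self.per_vertex_value = np.zeros(ids.size, dtype=np.float64)
        else:
            vals = np.asarray(self.per_vertex_value, dtype=np.float64).ravel()
            if vals.size != ids.size:
                raise ValueError("per_vertex_value length != number of vertex ids")
            self.per_vertex_value = vals[order]

    def __len__(self) -> int:
        return self.vertex_ids.size

    def indicator(self, n_vertices: int) -> np.ndarray:
        """Boolean membership array of length ``n_vertices``."""
        if self.vertex_ids.size and self.vertex_ids.max() >= n_vertices:
            raise ValueError(
                f"label {self.name!r} references vertex {int(self.vertex_ids.max())} "
                f"but mesh has {n_vertices} vertices"
            )
        ind = np.zeros(n_vertices, dtype=bool)
        ind[self.vertex_ids] = True
        return ind


@dataclass
class Parcellation:
    """Per-vertex region assignment with a region table.

    ``region_id_per_vertex`` holds small integer ids; id 0 means
    unassigned/"unknown". ``region_table`` maps id -> (name, (r, g, b)).
    """

    region_id_per_vertex: np.ndarray  # (N,) int32
    region_table: dict[int, tuple[str, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        self.region_id_per_vertex = np.asarray(self.region_id_per_vertex, dtype=np.int32).ravel()
        present = set(np.unique(self.region_id_per_vertex).tolist()) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"region ids {sorted(missing)} missing from region_table")

    @property
    def n_vertices(self) -> int:
        return self.region_id_per_vertex.size

    def region_ids(self) -> list[int]:
        """Sorted nonzero region ids in the table."""
        return sorted(i for i in self.region_table if i != 0)

    def name_of(self, region_id: int) -> str:
        return self.region_table[region_id][0]


@dataclass
class VoxelVolume:
    """A 3-D scalar intensity grid with voxel size in mm."""

    intensities: np.ndarray  # (X, Y, Z) float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D grid")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size components must be > 0, got {vs}")
        self.voxel_size = vs


@dataclass
class RegionStatsRow:
    """Per-region summary: vertex count, area, thickness, volume.

    ``volume_ml = surface_area_mm2 * mean_thickness_mm / 1000`` by
    construction. Regions emptied by exclusion carry ``num_vertices == 0``
    and ``thickness_defined == False`` (NaN thickness, zero area/volume).
    """

    region_name: str
    hemisphere: str
    num_vertices: int
    surface_area_mm2: float
    mean_thickness_mm: float
    thickness_sd_mm: float
    volume_ml: float
    thickness_defined: bool = True


# ---------------------------------------------------------------------------
# Binary triangle surface
# ---------------------------------------------------------------------------

_CREATE_STAMP = "created by lesioncorr"  # fixed stamp keeps output byte-reproducible


def _read_exact(f, n: int, path: Path, what: str) -> bytes:
    buf = f.read(n)
    if len(buf) != n:
        raise FormatError(
            f"{path}: truncated file: expected {n} bytes for {what} "
            f"at byte offset {f.tell() - len(buf)}, got {len(buf)}"
        )
    return buf


def _read_magic3(f, path: Path) -> int:
    b = _read_exact(f, 3, path, "magic number")
    return (b[0] << 16) | (b[1] << 8) | b[2]


def _write_magic3(f, magic: int) -> None:
    f.write(bytes([(magic >> 16) & 0xFF, (magic >> 8) & 0xFF, magic & 0xFF]))


def read_surface(path: str | Path) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface file."""
    path = Path(path)
    with open(path, "rb") as f:
        magic = _read_magic3(f, path)
        if magic != TRIANGLE_MAGIC:
            raise FormatError(
                f"{path}: bad magic 0x{magic:06X} at byte offset 0 "
                f"(expected triangle-surface magic 0x{TRIANGLE_MAGIC:06X})"
            )
        # creation stamp: one text line, followed by an optional blank line
        line = f.readline()
        nxt = f.read(1)
        if nxt != b"\n":
            f.seek(-len(nxt), 1)
        header_end = f.tell()
        nv, nf = struct.unpack(">ii", _read_exact(f, 8, path, "vertex/face counts"))
        if nv < 0 or nf < 0:
            raise FormatError(f"{path}: negative count at byte offset {header_end}")
        coords = np.frombuffer(
            _read_exact(f, 12 * nv, path, f"{nv} vertex coordinates"), dtype=">f4"
        ).reshape(nv, 3)
        faces_off = f.tell()
        faces = np.frombuffer(
            _read_exact(f, 12 * nf, path, f"{nf} faces"), dtype=">i4"
        ).reshape(nf, 3)
    if nf and (faces.min() < 0 or faces.max() >= nv):
        bad = int(np.where((faces < 0) | (faces >= nv))[0][0])
        raise FormatError(
            f"{path}: face vertex index out of range [0, {nv}) "
            f"at byte offset {faces_off + 12 * bad}"
        )
    return SurfaceMesh(coords.astype(np.float64), faces.astype(np.int32))


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a FreeSurfer binary triangle surface file (big-endian)."""
    path = Path(path)
    mesh.validate()
    with open(path, "wb") as f:
        _write_magic3(f, TRIANGLE_MAGIC)
        f.write((_CREATE_STAMP + "\n\n").encode())
        f.write(struct.pack(">ii", mesh.n_vertices, mesh.n_faces))
        f.write(np.ascontiguousarray(mesh.vertex_coords, dtype=">f4").tobytes())
        f.write(np.ascontiguousarray(mesh.faces, dtype=">i4").tobytes())


# ---------------------------------------------------------------------------
# Per-vertex scalar ("curv", new format)
# ---------------------------------------------------------------------------


def read_curv(path: str | Path, units: str = "dimensionless") -> VertexScalarField:
    """Read a new-format FreeSurfer per-vertex scalar file."""
    path = Path(path)
    with open(path, "rb") as f:
        magic = _read_magic3(f, path)
        if magic != CURV_MAGIC:
            raise FormatError(
                f"{path}: bad magic 0x{magic:06X} at byte offset 0 "
                f"(expected curv magic 0x{CURV_MAGIC:06X})"
            )
        nv, _fnum, vpv = struct.unpack(">iii", _read_exact(f, 12, path, "curv header"))
        if vpv != 1:
            raise FormatError(f"{path}: vals_per_vertex must be 1, got {vpv}")
        if nv < 0:
            raise FormatError(f"{path}: negative vertex count at byte offset 3")
        vals = np.frombuffer(_read_exact(f, 4 * nv, path, f"{nv} values"), dtype=">f4")
        if f.read(1):
            raise FormatError(f"{path}: trailing bytes after {nv} values")
    return VertexScalarField(vals.astype(np.float64), units=units)


def write_curv(field: VertexScalarField, path: str | Path, fnum: int = 0) -> None:
    """Write a new-format FreeSurfer per-vertex scalar file (big-endian)."""
    path = Path(path)
    with open(path, "wb") as f:
        _write_magic3(f, CURV_MAGIC)
        f.write(struct.pack(">iii", len(field), fnum, 1))
        f.write(np.ascontiguousarray(field.values, dtype=">f4").tobytes())


# ---------------------------------------------------------------------------
# ASCII label
# ---------------------------------------------------------------------------


def parse_label_name(filename: str) -> tuple[str, str, int | None]:
    """Split a label filename into (hemisphere, stem, lesion ordinal).

    ``"rh.lesion-03.label"`` -> ``("rh", "lesion-03", 3)``; a non-lesion stem
    yields ordinal ``None``.
    """
    m = _LABEL_NAME_RE.match(filename)
    if not m:
        raise FormatError(
            f"label filename {filename!r} does not match '(lh|rh).<name>.label'"
        )
    hemi, stem = m.group(1), m.group(2)
    lm = _LESION_STEM_RE.match(stem)
    return hemi, stem, int(lm.group(1)) if lm else None


def read_label(path: str | Path, hemisphere: str | None = None) -> SurfaceLabel:
    """Read a FreeSurfer ASCII label file.

    The hemisphere is inferred from the ``lh.``/``rh.`` filename prefix (the
    format itself carries no hemisphere field); a caller-declared
    ``hemisphere`` that disagrees with the prefix is an error.
    """
    path = Path(path)
    try:
        hemi, stem, _ = parse_label_name(path.name)
    except FormatError:
        if hemisphere is None:
            raise
        hemi, stem = hemisphere, path.stem
    if hemisphere is not None and hemisphere != hemi:
        raise ValueError(
            f"{path}: filename prefix says hemisphere {hemi!r} "
            f"but caller declared {hemisphere!r}"
        )
    with open(path, "rt") as f:
        f.readline()  # comment line
        count_line = f.readline()
        try:
            count = int(count_line.strip())
        except ValueError:
            raise FormatError(f"{path}: bad vertex count line {count_line!r}") from None
        rows = [ln.split() for ln in f if ln.strip()]
    if len(rows) != count:
        raise FormatError(f"{path}: header says {count} vertices, found {len(rows)} rows")
    if count == 0:
        raise FormatError(f"{path}: empty label")
    ids = np.array([int(r[0]) for r in rows], dtype=np.int64)
    vals = np.array([float(r[4]) for r in rows], dtype=np.float64)
    if ids.min() < 0:
        raise FormatError(f"{path}: negative vertex index {int(ids.min())}")
    if np.unique(ids).size != ids.size:
        raise FormatError(f"{path}: duplicate vertex index")
    return SurfaceLabel(name=f"{hemi}.{stem}", hemisphere=hemi, vertex_ids=ids, per_vertex_value=vals)


def write_label(label: SurfaceLabel, mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a FreeSurfer ASCII label, taking coordinates from ``mesh``."""
    path = Path(path)
    if len(label) == 0:
        raise FormatError("empty label")
    if label.vertex_ids.max() >= mesh.n_vertices:
        raise ValueError(
            f"label vertex {int(label.vertex_ids.max())} out of mesh range "
            f"[0, {mesh.n_vertices})"
        )
    with open(path, "wt", newline="\n") as f:
        f.write(f"#!ascii label {label.name}, vox2ras=TkReg\n")
        f.write(f"{len(label)}\n")
        for vid, val in zip(label.vertex_ids, label.per_vertex_value):
            x, y, z = mesh.vertex_coords[vid]
            f.write(f"{int(vid)}  {x:.6f}  {y:.6f}  {z:.6f} {val:.10f}\n")


# ---------------------------------------------------------------------------
# Binary annotation (+ colortable)
# ---------------------------------------------------------------------------

_TAG_OLD_COLORTABLE = 1
_CTAB_VERSION = -2  # "new-style" colortable


def _pack_rgb(r: int, g: int, b: int) -> int:
    # FreeSurfer annotation code: R + G*256 + B*65536, no alpha
    return int(r) + int(g) * 256 + int(b) * 65536


def read_annot(path: str | Path) -> Parcellation:
    """Read a binary FreeSurfer annotation with a new-style colortable.

    Region ids are the colortable structure indices; vertices whose packed
    color code equals the id-0 entry's code (or whose code is 0 with no such
    entry) come back as unassigned id 0.
    """
    path = Path(path)
    with open(path, "rb") as f:
        def ri() -> int:
            return struct.unpack(">i", _read_exact(f, 4, path, "int32"))[0]

        nv = ri()
        if nv < 0:
            raise FormatError(f"{path}: negative vertex count")
        data = np.frombuffer(
            _read_exact(f, 8 * nv, path, f"{nv} (vertex, code) pairs"), dtype=">i4"
        ).reshape(nv, 2)
        codes = data[:, 1].astype(np.int64)
        tag = ri()
        if tag != _TAG_OLD_COLORTABLE:
            raise FormatError(f"{path}: missing colortable (tag {tag})")
        version = ri()
        if version != _CTAB_VERSION:
            raise FormatError(f"{path}: unsupported colortable version {version}")
        ri()  # max structure index (unused; derived from entries)
        fname_len = ri()
        _read_exact(f, fname_len, path, "colortable filename")
        n_entries = ri()
        table: dict[int, tuple[str, tuple[int, int, int]]] = {}
        code_to_id: dict[int, int] = {}
        for _ in range(n_entries):
            idx = ri()
            name_len = ri()
            name = _read_exact(f, name_len, path, "structure name").rstrip(b"\x00").decode()
            r, g, b, _t = struct.unpack(">iiii", _read_exact(f, 16, path, "RGBT"))
            table[idx] = (name, (r, g, b))
            code_to_id[_pack_rgb(r, g, b)] = idx
    region_ids = np.zeros(nv, dtype=np.int32)
    for code in np.unique(codes):
        if int(code) in code_to_id:
            region_ids[codes == code] = code_to_id[int(code)]
        elif code == 0:
            pass  # unannotated vertices are written with code 0
        else:
            raise FormatError(
                f"{path}: color code {int(code)} absent from colortable"
            )
    return Parcellation(region_ids, table)


def write_annot(parc: Parcellation, path: str | Path) -> None:
    """Write a binary FreeSurfer annotation with a new-style colortable.

    Unassigned vertices (id 0) are written with the id-0 table entry's color
    code if present, else with code 0.
    """
    path = Path(path)
    ids = parc.region_id_per_vertex
    code_of = {i: _pack_rgb(*rgb) for i, (_n, rgb) in parc.region_table.items()}
    codes = np.zeros(ids.size, dtype=np.int64)
    for i, code in code_of.items():
        codes[ids == i] = code
    with open(path, "wb") as f:
        def wi(v: int) -> None:
            f.write(struct.pack(">i", v))

        def ws(s: str) -> None:
            b = s.encode() + b"\x00"
            wi(len(b))
            f.write(b)

        wi(ids.size)
        pairs = np.empty((ids.size, 2), dtype=">i4")
        pairs[:, 0] = np.arange(ids.size)
        pairs[:, 1] = codes
        f.write(pairs.tobytes())
        wi(_TAG_OLD_COLORTABLE)
        wi(_CTAB_VERSION)
        entries = sorted(parc.region_table)
        wi(max(entries, default=0) + 1)  # max structure index bound
        ws("NOFILE")
        wi(len(entries))
        for idx in entries:
            name, (r, g, b) = parc.region_table[idx]
            wi(idx)
            ws(name)
            f.write(struct.pack(">iiii", r, g, b, 0))


# ---------------------------------------------------------------------------
# Stats tables
# ---------------------------------------------------------------------------

_STATS_COLUMNS = [
    "region",
    "num_vertices",
    "surface_area_mm2",
    "mean_thickness_mm",
    "thickness_sd_mm",
    "volume_ml",
]


def write_stats_table(rows: Sequence[RegionStatsRow], path: str | Path) -> None:
    """Write per-region statistics as a TSV, one table per hemisphere.

    All rows must come from a single hemisphere; columns are region,
    num_vertices, surface_area_mm2, mean_thickness_mm, thickness_sd_mm,
    volume_ml.
    """
    hemis = {r.hemisphere for r in rows}
    if len(hemis) > 1:
        raise ValueError(f"rows mix hemispheres {sorted(hemis)}; one table per hemisphere")
    df = pd.DataFrame(
        [
            {
                "region": r.region_name,
                "num_vertices": r.num_vertices,
                "surface_area_mm2": r.surface_area_mm2,
                "mean_thickness_mm": r.mean_thickness_mm,
                "thickness_sd_mm": r.thickness_sd_mm,
                "volume_ml": r.volume_ml,
            }
            for r in rows
        ],
        columns=_STATS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g", lineterminator="\n")


def read_stats_table(path: str | Path) -> pd.DataFrame:
    """Read a stats TSV written by :func:`write_stats_table`."""
    return pd.read_csv(path, sep="\t")
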