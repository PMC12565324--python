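"""Domain types and I/O for meshes, landmark sets and cohort tables.

Meshes are plain triangle soups (STL ASCII/binary, ASCII PLY); landmark
configurations are ordered point sets with a fixed/semi-landmark split and
per-point patch tags.  All coordinates are in millimetres.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "TemplateDefinition",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "CohortTable",
    "MeshFormatError",
    "LandmarkFormatError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "mirror_mesh",
    "mirror_configuration",
    "closest_point_on_mesh",
    "closest_points",
]

#: dedup tolerance for STL facet vertices (mm)
VERTEX_DEDUP_TOL = 1e-9
#: triangles with area below this are dropped at load time (mm^2)
DEGENERATE_AREA_TOL = 1e-14


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed."""


class LandmarkFormatError(ValueError):
    """Raised when a landmark file cannot be parsed or validated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (n, 3) float, ``triangles`` (m, 3) int."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.shape[0] < 1:
            raise MeshFormatError("mesh must contain at least one triangle")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise MeshFormatError("triangle index out of vertex range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def triangle_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def triangle_normals(self) -> np.ndarray:
        """Unit normals following the triangle winding (right-hand rule)."""
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return n / norms


@dataclass
class LandmarkConfiguration:
    """Ordered landmark set for one specimen.

    Rows ``0..n_fixed-1`` are fixed landmarks (patch id 0); the remaining rows
    are semi-landmarks tagged with their patch id.  Row order must be
    identical across every specimen of a study.
    """

    specimen_id: str
    coordinates: np.ndarray
    patch_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.patch_ids = np.asarray(self.patch_ids, dtype=np.int64).reshape(-1)
        if len(self.patch_ids) != len(self.coordinates):
            raise LandmarkFormatError("patch_ids length must match coordinate rows")
        if not np.all(np.isfinite(self.coordinates)):
            raise LandmarkFormatError(
                f"non-finite coordinate in configuration {self.specimen_id!r}"
            )

    @property
    def n_landmarks(self) -> int:
        return len(self.coordinates)

    @property
    def n_fixed(self) -> int:
        return int(np.sum(self.patch_ids == 0))

    @property
    def fixed(self) -> np.ndarray:
        return self.coordinates[self.patch_ids == 0]

    @property
    def semilandmarks(self) -> np.ndarray:
        return self.coordinates[self.patch_ids != 0]


@dataclass
class TemplateDefinition:
    """Template surface with 10 labelled fixed landmarks and 200 patch semi-landmarks."""

    mesh: TriangleMesh
    fixed_landmarks: np.ndarray  # (10, 3)
    fixed_labels: tuple[str, ...]
    semilandmarks: np.ndarray  # (200, 3)
    semilandmark_patches: np.ndarray  # (200,) values in {1, 2}

    def __post_init__(self) -> None:
        self.fixed_landmarks = np.asarray(self.fixed_landmarks, float).reshape(-1, 3)
        self.semilandmarks = np.asarray(self.semilandmarks, float).reshape(-1, 3)
        self.semilandmark_patches = np.asarray(self.semilandmark_patches, np.int64)
        if len(self.fixed_landmarks) != 10:
            raise ValueError("template requires exactly 10 fixed landmarks")
        if len(self.semilandmarks) != 200:
            raise ValueError("template requires exactly 200 semi-landmarks")
        patches = set(self.semilandmark_patches.tolist())
        if patches != {1, 2}:
            raise ValueError("semi-landmarks must cover both patches 1 and 2")

    def configuration(self, specimen_id: str = "template") -> LandmarkConfiguration:
        coords = np.vstack([self.fixed_landmarks, self.semilandmarks])
        patch = np.concatenate([np.zeros(10, np.int64), self.semilandmark_patches])
        return LandmarkConfiguration(specimen_id, coords, patch)

    def all_points(self) -> np.ndarray:
        return np.vstack([self.fixed_landmarks, self.semilandmarks])


@dataclass
class SpecimenRecord:
    """One unilateral cavity of one patient."""

    specimen_id: str
    patient_id: str
    side: str  # "right" | "left"
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded specimen must carry a reason")


@dataclass
class CohortTable:
    """Per-patient demographics: sex in {female, male, unknown}, age in years (NaN = missing)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"patient_id", "sex", "age"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        if self.table["patient_id"].duplicated().any():
            raise ValueError("patient_id must be unique in cohort table")

    def lookup(self, patient_id: str) -> pd.Series:
        sub = self.table[self.table["patient_id"] == patient_id]
        if sub.empty:
            raise KeyError(patient_id)
        return sub.iloc[0]


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------


def _clean_mesh(vertices: np.ndarray, triangles: np.ndarray, path: str) -> TriangleMesh:
    """Deduplicate vertices within tolerance and drop degenerate triangles."""
    if len(triangles) == 0:
        raise MeshFormatError(f"no triangles in mesh file {path!r}")
    quant = np.round(vertices / VERTEX_DEDUP_TOL).astype(np.int64)
    _, first, inverse = np.unique(quant, axis=0, return_index=True, return_inverse=True)
    vertices = vertices[np.sort(first)]
    # remap through the sorted order so vertex order is stable
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    triangles = rank[inverse][triangles]

    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    keep = areas > DEGENERATE_AREA_TOL
    triangles = triangles[keep]
    if len(triangles) == 0:
        raise MeshFormatError(f"all triangles degenerate in {path!r}")
    return TriangleMesh(vertices, triangles)


def _read_stl_binary(data: bytes, path: str) -> tuple[np.ndarray, np.ndarray]:
    (n_tri,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * n_tri
    if len(data) < expected:
        raise MeshFormatError(f"truncated binary STL {path!r}")
    raw = np.frombuffer(data, dtype=np.uint8, count=50 * n_tri, offset=84)
    records = raw.reshape(n_tri, 50)[:, :48].copy().view("<f4").reshape(n_tri, 12)
    verts = records[:, 3:12].astype(float).reshape(-1, 3)
    tris = np.arange(3 * n_tri, dtype=np.int64).reshape(-1, 3)
    return verts, tris


def _read_stl_ascii(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise MeshFormatError(f"malformed vertex line in {path!r}: {line!r}")
            verts.append([float(x) for x in parts[1:]])
    if not verts or len(verts) % 3:
        raise MeshFormatError(f"ASCII STL {path!r} has no complete facets")
    v = np.array(verts, float)
    t = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return v, t


def _read_ply_ascii(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"not a PLY file: {path!r}")
    n_vert = n_face = None
    i = 1
    props_before_xyz = 0
    current_element = None
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise MeshFormatError(f"only ASCII PLY is supported: {path!r}")
        if parts[0] == "element":
            current_element = parts[1]
            if parts[1] == "vertex":
                n_vert = int(parts[2])
            elif parts[1] == "face":
                n_face = int(parts[2])
        if parts[0] == "end_header":
            break
    else:
        raise MeshFormatError(f"PLY header never ends in {path!r}")
    if n_vert is None or n_face is None:
        raise MeshFormatError(f"PLY missing vertex/face elements in {path!r}")
    body = [ln.split() for ln in lines[i:] if ln.strip()]
    if len(body) < n_vert + n_face:
        raise MeshFormatError(f"truncated PLY body in {path!r}")
    verts = np.array([[float(x) for x in row[:3]] for row in body[:n_vert]])
    tris: list[list[int]] = []
    for row in body[n_vert : n_vert + n_face]:
        cnt = int(row[0])
        idx = [int(x) for x in row[1 : 1 + cnt]]
        for j in range(1, cnt - 1):  # fan-triangulate polygons
            tris.append([idx[0], idx[j], idx[j + 1]])
    return verts, np.array(tris, np.int64).reshape(-1, 3)


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read an STL (ASCII or binary) or ASCII PLY surface mesh.

    Vertices are deduplicated within ``VERTEX_DEDUP_TOL`` and degenerate
    triangles dropped.
    """
    path = Path(path)
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise MeshFormatError(f"cannot read mesh file {str(path)!r}: {exc}") from exc
    if len(data) == 0:
        raise MeshFormatError(f"empty mesh file {str(path)!r}")

    if path.suffix.lower() == ".ply" or data[:3] == b"ply":
        verts, tris = _read_ply_ascii(data.decode("utf-8", "replace"), str(path))
        return _clean_mesh(verts, tris, str(path))

    # STL: the "solid" prefix is not reliable; trust the binary length check.
    if len(data) >= 84:
        (n_tri,) = struct.unpack_from("<I", data, 80)
        if len(data) == 84 + 50 * n_tri and n_tri > 0:
            verts, tris = _read_stl_binary(data, str(path))
            return _clean_mesh(verts, tris, str(path))
    text = data.decode("utf-8", "replace")
    if "facet" not in text and "vertex" not in text:
        raise MeshFormatError(f"unrecognized mesh format in {str(path)!r}")
    verts, tris = _read_stl_ascii(text, str(path))
    return _clean_mesh(verts, tris, str(path))


def write_mesh(mesh: TriangleMesh, path: str | Path, binary: bool = False) -> None:
    """Write a mesh as STL (ASCII by default) or ASCII PLY by extension."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_ply_ascii(mesh, path)
        return
    if binary:
        _write_stl_binary(mesh, path)
    else:
        _write_stl_ascii(mesh, path)


def _fmt(v: float) -> str:
    """Shortest round-trippable decimal text (stable under re-parsing)."""
    return repr(float(v))


def _write_stl_ascii(mesh: TriangleMesh, path: Path) -> None:
    normals = mesh.triangle_normals()
    a, b, c = mesh.triangle_corners()
    buf = io.StringIO()
    buf.write("solid morphocavity\n")
    for i in range(mesh.n_triangles):
        n = normals[i]
        buf.write(f"  facet normal {_fmt(n[0])} {_fmt(n[1])} {_fmt(n[2])}\n")
        buf.write("    outer loop\n")
        for p in (a[i], b[i], c[i]):
            buf.write(f"      vertex {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        buf.write("    endloop\n")
        buf.write("  endfacet\n")
    buf.write("endsolid morphocavity\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    normals = mesh.triangle_normals().astype("<f4")
    a, b, c = (x.astype("<f4") for x in mesh.triangle_corners())
    n_tri = mesh.n_triangles
    out = bytearray(struct.pack("<80sI", b"morphocavity binary STL", n_tri))
    rec = np.zeros((n_tri, 12), "<f4")
    rec[:, 0:3] = normals
    rec[:, 3:6] = a
    rec[:, 6:9] = b
    rec[:, 9:12] = c
    raw = rec.view(np.uint8).reshape(n_tri, 48)
    padded = np.zeros((n_tri, 50), np.uint8)
    padded[:, :48] = raw
    out += padded.tobytes()
    Path(path).write_bytes(bytes(out))


def _write_ply_ascii(mesh: TriangleMesh, path: Path) -> None:
    buf = io.StringIO()
    buf.write("ply\nformat ascii 1.0\n")
    buf.write(f"element vertex {mesh.n_vertices}\n")
    buf.write("property float x\nproperty float y\nproperty float z\n")
    buf.write(f"element face {mesh.n_triangles}\n")
    buf.write("property list uchar int vertex_indices\nend_header\n")
    for v in mesh.vertices:
        buf.write(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")
    for t in mesh.triangles:
        buf.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# landmark I/O
# ---------------------------------------------------------------------------


def write_landmarks(
    config: LandmarkConfiguration, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a configuration as CSV (canonical, carries patch ids) or LM3 text.

    Round trips through :func:`read_landmarks` are bit-identical on the
    decimal text because coordinates are printed with ``repr``.
    """
    path = Path(path)
    if not np.all(np.isfinite(config.coordinates)):
        raise LandmarkFormatError("refusing to write non-finite coordinates")
    if dialect == "csv":
        lines = ["id,patch,x,y,z"]
        for i, (p, xyz) in enumerate(zip(config.patch_ids, config.coordinates)):
            lines.append(f"{i},{p},{_fmt(xyz[0])},{_fmt(xyz[1])},{_fmt(xyz[2])}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "tps":
        lines = [f"LM3={config.n_landmarks}"]
        for xyz in config.coordinates:
            lines.append(f"{_fmt(xyz[0])} {_fmt(xyz[1])} {_fmt(xyz[2])}")
        lines.append(f"ID={config.specimen_id}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise LandmarkFormatError(f"unknown landmark dialect {dialect!r}")


def read_landmarks(path: str | Path, dialect: str = "csv") -> LandmarkConfiguration:
    """Inverse of :func:`write_landmarks`."""
    if dialect not in ("csv", "tps"):
        raise LandmarkFormatError(f"unknown landmark dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if dialect == "csv":
        df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
        needed = {"id", "patch", "x", "y", "z"}
        if not needed.issubset(df.columns):
            raise LandmarkFormatError(
                f"landmark CSV {str(path)!r} missing columns {sorted(needed - set(df.columns))}"
            )
        df = df.sort_values("id")
        coords = df[["x", "y", "z"]].to_numpy(float)
        return LandmarkConfiguration(path.stem, coords, df["patch"].to_numpy(np.int64))
    if dialect == "tps":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("LM3="):
            raise LandmarkFormatError(f"missing LM3 header in {str(path)!r}")
        n = int(lines[0].split("=", 1)[1])
        coord_lines = [ln for ln in lines[1:] if not ln.startswith("ID=")]
        if len(coord_lines) != n:
            raise LandmarkFormatError(
                f"LM3 header promises {n} points but {len(coord_lines)} found in {str(path)!r}"
            )
        ids = [ln for ln in lines[1:] if ln.startswith("ID=")]
        specimen_id = ids[0].split("=", 1)[1] if ids else path.stem
        coords = np.array([[float(x) for x in ln.split()] for ln in coord_lines])
        return LandmarkConfiguration(specimen_id, coords, np.zeros(n, np.int64))
    raise LandmarkFormatError(f"unknown landmark dialect {dialect!r}")


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometric utilities
# ---------------------------------------------------------------------------


def mirror_mesh(mesh: TriangleMesh, plane: str = "sagittal") -> TriangleMesh:
    """Mirror across the sagittal (X = 0) plane, flipping winding to preserve normals."""
    if plane != "sagittal":
        raise ValueError(f"unsupported mirror plane {plane!r}")
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    t = mesh.triangles[:, [0, 2, 1]].copy()
    return TriangleMesh(v, t)


def mirror_configuration(
    config: LandmarkConfiguration, plane: str = "sagittal"
) -> LandmarkConfiguration:
    """Mirror landmark coordinates across the sagittal (X = 0) plane."""
    if plane != "sagittal":
        raise ValueError(f"unsupported mirror plane {plane!r}")
    coords = config.coordinates.copy()
    coords[:, 0] = -coords[:, 0]
    return replace(config, coordinates=coords)


def _closest_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c), broadcast over any
    leading axes (points x triangles).

    Exact by construction: the orthogonal foot on the triangle plane is used
    when its barycentric coordinates are non-negative; otherwise the closest
    point lies on the boundary and the best of the three clamped edge
    projections is taken.
    """

    def _seg(p, s0, s1):
        d = s1 - s0
        dd = np.einsum("...j,...j->...", d, d)
        t = np.einsum("...j,...j->...", p - s0, d) / np.where(dd > 0, dd, 1.0)
        return s0 + np.clip(t, 0.0, 1.0)[..., None] * d

    ab = b - a
    ac = c - a
    ap = p - a
    d00 = np.einsum("...j,...j->...", ab, ab)
    d01 = np.einsum("...j,...j->...", ab, ac)
    d11 = np.einsum("...j,...j->...", ac, ac)
    d20 = np.einsum("...j,...j->...", ap, ab)
    d21 = np.einsum("...j,...j->...", ap, ac)
    den = d00 * d11 - d01 * d01
    safe = np.where(np.abs(den) > 0, den, 1.0)
    v = (d11 * d20 - d01 * d21) / safe
    w = (d00 * d21 - d01 * d20) / safe
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (np.abs(den) > 0)
    foot = a + v[..., None] * ab + w[..., None] * ac

    e1 = _seg(p, a, b)
    e2 = _seg(p, a, c)
    e3 = _seg(p, b, c)
    d1 = np.einsum("...j,...j->...", e1 - p, e1 - p)
    d2 = np.einsum("...j,...j->...", e2 - p, e2 - p)
    d3 = np.einsum("...j,...j->...", e3 - p, e3 - p)
    best = np.where((d2 < d1)[..., None], e2, e1)
    best_d = np.minimum(d1, d2)
    best = np.where((d3 < best_d)[..., None], e3, best)
    return np.where(inside[..., None], foot, best)


def closest_point_on_mesh(
    p: Sequence[float], mesh: TriangleMesh
) -> tuple[np.ndarray, int, float]:
    """Closest point on the mesh surface to ``p``.

    Returns ``(point, triangle_index, distance)``; distance ties are broken
    by the lowest triangle index.
    """
    p = np.asarray(p, float).reshape(3)
    a, b, c = mesh.triangle_corners()
    candidates = _closest_on_triangles(p, a, b, c)
    d2 = np.einsum("ij,ij->i", candidates - p, candidates - p)
    idx = int(np.argmin(d2))
    return candidates[idx], idx, float(np.sqrt(d2[idx]))


def closest_points(points: np.ndarray, mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`closest_point_on_mesh` for many query points.

    Returns ``(projected (m,3), triangle indices (m,), distances (m,))``.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    a, b, c = mesh.triangle_corners()
    out = np.empty_like(points)
    tri = np.empty(len(points), np.int64)
    dist = np.empty(len(points))

    # prune with a KD-tree: any triangle holding the closest surface point
    # has its centroid within (nearest-vertex distance + max centroid-to-
    # corner radius) of the query, so only those candidates need the exact
    # point-triangle test.  The bound keeps the search exact.
    centroids = (a + b + c) / 3.0
    radius = float(
        np.sqrt(
            np.max(
                np.maximum(
                    np.einsum("ij,ij->i", a - centroids, a - centroids),
                    np.maximum(
                        np.einsum("ij,ij->i", b - centroids, b - centroids),
                        np.einsum("ij,ij->i", c - centroids, c - centroids),
                    ),
                )
            )
        )
    )
    vtree = cKDTree(mesh.vertices)
    ctree = cKDTree(centroids)
    upper, _ = vtree.query(points)
    candidate_lists = ctree.query_ball_point(
        points, upper + radius + 1e-9, return_sorted=True
    )
    for i, (p, cand_idx) in enumerate(zip(points, candidate_lists)):
        idx = np.asarray(cand_idx, np.int64)
        cand = _closest_on_triangles(p, a[idx], b[idx], c[idx])
        d2 = np.einsum("ij,ij->i", cand - p, cand - p)
        k = int(np.argmin(d2))
        out[i] = cand[k]
        tri[i] = idx[k]
        dist[i] = np.sqrt(d2[k])
    return out, tri, dist
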