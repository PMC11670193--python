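"""File-format plumbing: binary STL, centerline/solution/segmentation CSV,
legacy-VTK surface export with a per-face WSS scalar, and output manifests.

CSV dialect is fixed: UTF-8, header row, '.' decimal, full-precision
``%.17g`` floats so that round-tripped files reproduce downstream outputs
bit-identically.
"""
from __future__ import annotations

import csv
import hashlib
import json
import struct
from pathlib import Path

import numpy as np

from .flow import FlowSolution
from .geometry import SegmentationScheme, VesselGeometry

__all__ = [
    "write_stl",
    "read_stl",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_solution_csv",
    "write_segmentation_csv",
    "write_vtk_surface",
    "sha256_of",
    "write_manifest",
]

CENTERLINE_COLUMNS = ("station_index", "x_mm", "y_mm", "z_mm", "arclength_mm", "radius_mm")
FLOAT_FMT = "%.17g"


def write_stl(path: str | Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Write a binary (little-endian, float32) STL surface."""
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    tri = v[f]  # (n, 3, 3)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    n = n / norm
    rec = np.zeros(
        f.shape[0],
        dtype=np.dtype(
            [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        ),
    )
    rec["normal"] = n.astype(np.float32)
    rec["v"] = tri.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(b"veinflow binary stl".ljust(80, b"\0"))
        fh.write(struct.pack("<I", f.shape[0]))
        fh.write(rec.tobytes())


def read_stl(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a binary STL; vertices are deduplicated exactly (bit-equal)."""
    with open(path, "rb") as fh:
        header = fh.read(80)
        if header[:5] == b"solid":
            # tolerate ASCII STL written by other tools
            fh.seek(0)
            return _read_ascii_stl(fh.read().decode("utf-8", errors="replace"))
        (count,) = struct.unpack("<I", fh.read(4))
        rec = np.frombuffer(
            fh.read(count * 50),
            dtype=np.dtype(
                [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            ),
            count=count,
        )
    tri = rec["v"].astype(np.float64).reshape(-1, 3)
    verts, inverse = np.unique(tri, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3).astype(np.int64)
    return verts, faces


def _read_ascii_stl(text: str) -> tuple[np.ndarray, np.ndarray]:
    pts = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            pts.append([float(x) for x in parts[1:4]])
    tri = np.asarray(pts, dtype=np.float64)
    if tri.shape[0] % 3:
        raise ValueError("malformed ASCII STL: vertex count not divisible by 3")
    verts, inverse = np.unique(tri, axis=0, return_inverse=True)
    return verts, inverse.reshape(-1, 3).astype(np.int64)


def write_centerline_csv(path: str | Path, geometry: VesselGeometry) -> None:
    """Write the station table (mm units, full precision)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CENTERLINE_COLUMNS)
        for i in range(geometry.n_stations):
            x, y, z = geometry.centerline[i]
            w.writerow(
                [i]
                + [
                    FLOAT_FMT % val
                    for val in (x, y, z, geometry.arclength[i], geometry.radius[i])
                ]
            )


def read_centerline_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a station table; returns ``(points_mm, arclength_mm, radius_mm)``.

    Raises ``ValueError`` naming any missing column.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CENTERLINE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"centerline CSV missing column(s): {', '.join(missing)}")
        rows = list(reader)
    if len(rows) < 2:
        raise ValueError("centerline CSV must contain at least two stations")
    pts = np.array([[float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])] for r in rows])
    s = np.array([float(r["arclength_mm"]) for r in rows])
    rad = np.array([float(r["radius_mm"]) for r in rows])
    return pts, s, rad


def write_solution_csv(
    path: str | Path, geometry: VesselGeometry, solution: FlowSolution
) -> None:
    """Per-station solution export (mm / Pa / m/s; reported pressure scale)."""
    p = solution.reported_pressure
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["s_mm", "radius_mm", "velocity_mps", "pressure_pa", "wss_pa"])
        for i in range(geometry.n_stations):
            w.writerow(
                [
                    FLOAT_FMT % geometry.arclength[i],
                    FLOAT_FMT % geometry.radius[i],
                    FLOAT_FMT % solution.velocity[i],
                    FLOAT_FMT % p[i],
                    FLOAT_FMT % solution.wss[i],
                ]
            )


def write_segmentation_csv(path: str | Path, scheme: SegmentationScheme) -> None:
    groups = {k: lab for lab, ks in scheme.groups.items() for k in ks}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["segment_index", "s_start_mm", "s_end_mm", "group"])
        for k in range(1, scheme.K + 1):
            w.writerow(
                [
                    k,
                    FLOAT_FMT % scheme.boundaries[k - 1],
                    FLOAT_FMT % scheme.boundaries[k],
                    groups[k],
                ]
            )


def write_vtk_surface(
    path: str | Path,
    geometry: VesselGeometry,
    face_scalars: np.ndarray | None = None,
    scalar_name: str = "wss_pa",
) -> None:
    """Legacy ASCII VTK PolyData export with an optional per-face scalar."""
    v = geometry.vertices
    f = geometry.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "veinflow surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {v.shape[0]} double",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in v]
    lines.append(f"POLYGONS {f.shape[0]} {4 * f.shape[0]}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    if face_scalars is not None:
        if face_scalars.shape[0] != f.shape[0]:
            raise ValueError("face scalar length must match face count")
        lines.append(f"CELL_DATA {f.shape[0]}")
        lines.append(f"SCALARS {scalar_name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{x:.9g}" for x in face_scalars]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path, seed: int, config: dict, files: list[Path], root: Path
) -> None:
    """JSON manifest with seeds, config and checksums of text outputs."""
    from . import __version__

    manifest = {
        "software": "veinflow",
        "version": __version__,
        "seed": seed,
        "config": config,
        "files": {
            str(p.relative_to(root)): sha256_of(p) for p in sorted(files)
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
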