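"""Centerline geometry, morphology metrics and equal-arclength segmentation.

A vein is represented by a triangulated surface plus an ordered centerline
polyline with a local radius at every station.  All geometric quantities in
this module are expressed in millimetres; conversion to SI happens at the
solver boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "VesselGeometry",
    "SegmentationScheme",
    "tortuosity_index",
    "area_ratio",
    "absolute_length",
    "actual_length",
    "divide_segments",
    "station_weights",
    "mesh_is_watertight",
    "mesh_volume",
    "cross_section",
    "planar_cap_area",
]

#: relative slack allowed when checking ``actual >= absolute``
_LENGTH_TOL = 1e-9


@dataclass(frozen=True)
class VesselGeometry:
    """Surface mesh plus centerline with per-station radius (millimetres).

    Parameters
    ----------
    vertices : (n_v, 3) float array
        Surface vertex coordinates in mm.
    faces : (n_f, 3) int array
        Triangle vertex indices (outward-oriented).
    centerline : (m, 3) float array
        Ordered centerline points, inlet first.
    radius : (m,) float array
        Local lumen radius at each station, mm.
    arclength : (m,) float array
        Cumulative arclength at each station, mm; starts at 0 and is
        strictly increasing.
    """

    vertices: np.ndarray
    faces: np.ndarray
    centerline: np.ndarray
    radius: np.ndarray
    arclength: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        c = np.asarray(self.centerline, dtype=float)
        r = np.asarray(self.radius, dtype=float)
        s = np.asarray(self.arclength, dtype=float)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "centerline", c)
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "arclength", s)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 2:
            raise ValueError("centerline must be an (m>=2, 3) array")
        if r.shape != (c.shape[0],) or s.shape != (c.shape[0],):
            raise ValueError("radius/arclength must match centerline stations")
        if not np.all(r > 0):
            raise ValueError("all station radii must be positive")
        if not np.all(np.diff(s) > 0):
            raise ValueError("arclength must be strictly increasing")
        if abs(s[0]) > 1e-12:
            raise ValueError("arclength must start at 0")

    @property
    def n_stations(self) -> int:
        return self.centerline.shape[0]

    @property
    def total_length(self) -> float:
        """Centerline arclength, mm."""
        return float(self.arclength[-1])

    @property
    def inlet_area(self) -> float:
        """Lumen cross-sectional area at the inlet station, mm^2."""
        return float(np.pi * self.radius[0] ** 2)

    @property
    def exit_area(self) -> float:
        """Lumen cross-sectional area at the outlet station, mm^2."""
        return float(np.pi * self.radius[-1] ** 2)


@dataclass(frozen=True)
class SegmentationScheme:
    """Division of the centerline into ``K`` equal-arclength segments.

    Segment indices run 1..K from the inlet (nidus-proximal) end to the
    outlet.  Segments are grouped into three consecutive thirds labelled
    A, B and C; with the default K=15 these are segments 1-5, 6-10 and
    11-15, C being the outflow-proximal ("posterior") portion.
    """

    K: int
    boundaries: np.ndarray  # (K+1,) arclength values, mm
    segment_of_station: np.ndarray  # (m,) int, 1..K

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        seg = np.asarray(self.segment_of_station, dtype=np.int64)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "segment_of_station", seg)

    @property
    def groups(self) -> Mapping[str, tuple[int, ...]]:
        """Mapping of group label to member segment indices (near-equal thirds)."""
        edges = np.linspace(0, self.K, 4).round().astype(int)
        labels = ("A", "B", "C")
        return {
            lab: tuple(range(edges[i] + 1, edges[i + 1] + 1))
            for i, lab in enumerate(labels)
        }

    def stations_in_segment(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.K:
            raise ValueError(f"segment index {k} outside 1..{self.K}")
        return np.flatnonzero(self.segment_of_station == k)


def tortuosity_index(actual_length: float, absolute_length: float) -> float:
    """Ratio of centerline arclength to straight inlet-outlet distance.

    Always >= 1; equals 1 only for a perfectly straight vessel.
    """
    if absolute_length <= 0:
        raise ValueError("absolute length must be positive")
    if actual_length <= 0:
        raise ValueError("actual length must be positive")
    if actual_length < absolute_length * (1.0 - 1e-9):
        raise ValueError(
            "actual length smaller than absolute length: inconsistent geometry"
        )
    return max(actual_length / absolute_length, 1.0)


def area_ratio(exit_area: float, inlet_area: float) -> float:
    """Outlet/inlet cross-sectional area ratio (dimensionless)."""
    if exit_area <= 0 or inlet_area <= 0:
        raise ValueError("cross-sectional areas must be positive")
    return exit_area / inlet_area


def absolute_length(geometry: VesselGeometry) -> float:
    """Straight-line distance between inlet and outlet, mm."""
    d = float(np.linalg.norm(geometry.centerline[-1] - geometry.centerline[0]))
    if d < 1e-9:  # mm; endpoints numerically coincident
        raise ValueError("degenerate centerline: coincident endpoints")
    return d


def actual_length(geometry: VesselGeometry) -> float:
    """Centerline arclength, mm."""
    return geometry.total_length


def divide_segments(geometry: VesselGeometry, K: int = 15) -> SegmentationScheme:
    """Divide the centerline into K equal-arclength segments.

    A station lying exactly on an interior boundary is assigned to the
    downstream (higher-index) segment; the final station belongs to
    segment K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if geometry.n_stations < K:
        raise ValueError(
            f"{geometry.n_stations} stations cannot populate {K} segments"
        )
    total = geometry.total_length
    boundaries = np.linspace(0.0, total, K + 1)
    # searchsorted(side='right') sends boundary stations downstream
    seg = np.searchsorted(boundaries, geometry.arclength, side="right")
    seg = np.clip(seg, 1, K).astype(np.int64)
    scheme = SegmentationScheme(K=K, boundaries=boundaries, segment_of_station=seg)
    counts = np.bincount(seg, minlength=K + 1)[1:]
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0]) + 1
        raise ValueError(f"segment {empty} contains no stations; add stations")
    return scheme


def station_weights(arclength: np.ndarray) -> np.ndarray:
    """Trapezoid arclength weight of each station (half-interval at the ends)."""
    s = np.asarray(arclength, dtype=float)
    w = np.empty_like(s)
    w[1:-1] = (s[2:] - s[:-2]) / 2.0
    w[0] = (s[1] - s[0]) / 2.0
    w[-1] = (s[-1] - s[-2]) / 2.0
    return w


# ---------------------------------------------------------------------------
# mesh utilities


def _edge_table(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(faces, dtype=np.int64)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)
    key = np.sort(e, axis=1)
    return e, key


def mesh_is_watertight(faces: np.ndarray) -> bool:
    """True if every undirected edge is shared by exactly two faces with
    opposite orientation (closed, consistently oriented 2-manifold)."""
    e, key = _edge_table(faces)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key_sorted = key[order]
    e_sorted = e[order]
    n = key_sorted.shape[0]
    if n % 2:
        return False
    a = key_sorted[0::2]
    b = key_sorted[1::2]
    if not np.array_equal(a, b):
        return False
    # pair members must have opposite direction
    return bool(np.all(np.any(e_sorted[0::2] != e_sorted[1::2], axis=1)))


def mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume via the divergence theorem (mm^3)."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def cross_section(
    vertices: np.ndarray,
    faces: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    radius_hint: float,
) -> tuple[float, float]:
    """Slice the mesh with the plane ``(point, normal)`` and return
    ``(area_mm2, effective_radius_mm)`` of the local lumen cross-section.

    Only faces within ``4 * radius_hint`` of ``point`` are considered, so a
    tortuous tube is cut once even though the plane is infinite.  The
    intersection polygon is ordered by angle about its centroid (valid for
    the near-circular sections of tubular meshes).
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)

    d = (v - point) @ normal
    # vertices exactly in the plane (e.g. a station ring) would otherwise
    # leave no strictly crossing edge; nudge them to the positive side
    d[d == 0.0] = 1e-12 * max(radius_hint, 1.0)
    near = np.linalg.norm(v - point, axis=1) < 4.0 * radius_hint
    sign = np.sign(d)
    fs = sign[f]
    fnear = near[f].all(axis=1)
    crossing = fnear & ~(np.all(fs >= 0, axis=1) | np.all(fs <= 0, axis=1))
    if not np.any(crossing):
        raise ValueError("slicing plane does not intersect the mesh locally")

    pts = []
    for tri in f[crossing]:
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            da, db = d[a], d[b]
            if (da < 0) != (db < 0):
                t = da / (da - db)
                pts.append(v[a] + t * (v[b] - v[a]))
    pts_arr = np.array(pts)
    u, w = _plane_basis(normal)
    rel = pts_arr - point
    xy = np.stack([rel @ u, rel @ w], axis=1)
    center = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0])
    order = np.argsort(ang)
    xy = xy[order]
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area), float(np.sqrt(area / np.pi))


def planar_cap_area(
    vertices: np.ndarray,
    faces: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    tol: float = 1e-6,
) -> float:
    """Total area (mm^2) of faces lying entirely in the plane ``(point, normal)``.

    Used to audit the planar inlet/outlet caps of a tube mesh against the
    analytic station areas.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = np.abs((v - np.asarray(point, dtype=float)) @ normal)
    in_plane = d < tol
    cap = in_plane[f].all(axis=1)
    if not np.any(cap):
        raise ValueError("no cap faces found in the given plane")
    a, b, c = v[f[cap, 0]], v[f[cap, 1]], v[f[cap, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
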