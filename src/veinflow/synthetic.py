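"""Parametric generation of synthetic draining-vein geometries and cohorts.

Geometries are watertight tubes swept along a smooth 3D centerline (a
straight chord plus a seeded sum of transverse sine modes).  The radius
profile interpolates geometrically from the inlet radius to the outlet
radius implied by the target outlet/inlet area ratio, with optional
multiplicative stenosis / aneurysm bumps.  Everything is a deterministic
function of the parameters, including the seed.

Cohorts are drawn from per-group parameter distributions whose defaults
target the group medians of the study population this package emulates:
a "ruptured-like" group with strong distal taper and higher inlet
velocity, and an "unruptured-like" group with near-uniform caliber and
lower velocity.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import VesselGeometry

__all__ = [
    "Stenosis",
    "Aneurysm",
    "VesselParams",
    "DistSpec",
    "GroupConfig",
    "CohortConfig",
    "generate_vessel",
    "generate_cohort",
    "radius_profile",
    "centerline_points",
    "amplitude_for_tortuosity",
    "with_tortuosity",
    "semicircle_geometry",
    "tube_mesh",
    "default_cohort_config",
]


@dataclass(frozen=True)
class Stenosis:
    """Localized multiplicative narrowing: radius scaled by ``1 - severity``
    at ``position`` (normalized arclength), Gaussian falloff of ``width``."""

    position: float
    severity: float
    width: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.position < 1.0:
            raise ValueError("stenosis position must lie in (0, 1)")
        if not 0.0 <= self.severity < 1.0:
            raise ValueError("stenosis severity must lie in [0, 1): no full occlusion")
        if self.width <= 0:
            raise ValueError("stenosis width must be positive")


@dataclass(frozen=True)
class Aneurysm:
    """Localized multiplicative dilation: radius scaled by ``bulge`` at
    ``position``, Gaussian falloff of ``width``."""

    position: float
    bulge: float
    width: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.position < 1.0:
            raise ValueError("aneurysm position must lie in (0, 1)")
        if self.bulge <= 1.0:
            raise ValueError("aneurysm bulge factor must exceed 1")
        if self.width <= 0:
            raise ValueError("aneurysm width must be positive")


@dataclass(frozen=True)
class VesselParams:
    """Generative parameters of one synthetic vein.

    Lengths and radii in millimetres, velocity in m/s.  ``tortuosity_amplitude``
    is the transverse perturbation amplitude; the realized centerline always
    has arclength ``target_actual_length`` (the chord shrinks as the
    amplitude grows).
    """

    inlet_radius: float
    outlet_inlet_area_ratio: float = 1.0
    target_actual_length: float = 60.0
    tortuosity_amplitude: float = 0.0
    tortuosity_wavelengths: int = 2
    stenosis: Stenosis | None = None
    aneurysm: Aneurysm | None = None
    inlet_velocity: float = 0.05
    n_stations: int = 301
    n_circumference: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inlet_radius <= 0:
            raise ValueError("inlet radius must be positive")
        if self.outlet_inlet_area_ratio <= 0:
            raise ValueError("outlet/inlet area ratio must be positive")
        if self.target_actual_length <= 0:
            raise ValueError("target actual length must be positive")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity amplitude must be non-negative")
        if self.tortuosity_wavelengths < 1 or self.tortuosity_wavelengths > 3:
            raise ValueError("tortuosity wavelengths must be 1..3")
        if self.inlet_velocity < 0:
            raise ValueError("inlet velocity must be non-negative")
        if self.n_stations < 31:
            raise ValueError("need at least 31 stations (>=2K+1 for K=15)")
        if self.n_circumference < 8:
            raise ValueError("need at least 8 circumferential vertices")

    @property
    def outlet_radius(self) -> float:
        return self.inlet_radius * np.sqrt(self.outlet_inlet_area_ratio)


# ---------------------------------------------------------------------------
# centerline


def _mode_basis(wavelengths: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-mode weights (decaying 1/m) and transverse unit directions."""
    rng = np.random.default_rng(seed)
    m = np.arange(1, wavelengths + 1)
    weights = (1.0 / m) * (0.75 + 0.5 * rng.random(wavelengths))
    theta = rng.uniform(0.0, 2.0 * np.pi, wavelengths)
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return weights, dirs


def _transverse_offsets(
    t: np.ndarray, amplitude: float, weights: np.ndarray, dirs: np.ndarray
) -> np.ndarray:
    """(len(t), 2) transverse offsets; sine modes vanish at both endpoints."""
    out = np.zeros((t.size, 2))
    for m, (w, d) in enumerate(zip(weights, dirs), start=1):
        out += amplitude * w * np.sin(m * np.pi * t)[:, None] * d[None, :]
    return out


def _unit_tortuosity(alpha: float, weights: np.ndarray, dirs: np.ndarray) -> float:
    """Arclength of the unit-chord curve with amplitude/chord ratio ``alpha``."""
    t = np.linspace(0.0, 1.0, 2001)
    xy = _transverse_offsets(t, alpha, weights, dirs)
    pts = np.column_stack([xy, t])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _solve_chord(params: VesselParams) -> float:
    """Chord length (mm) such that the realized arclength equals the target."""
    A, L = params.tortuosity_amplitude, params.target_actual_length
    if A == 0.0:
        return L
    weights, dirs = _mode_basis(params.tortuosity_wavelengths, params.seed)
    # solve g(alpha)/alpha = L/A for alpha = amplitude/chord (monotone decreasing)
    target = L / A

    def h(alpha: float) -> float:
        return _unit_tortuosity(alpha, weights, dirs) / alpha - target

    lo, hi = 1e-9, 1.0
    while h(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("tortuosity amplitude too large for the target length")
    alpha = brentq(h, lo, hi, xtol=1e-12, rtol=1e-14)
    return A / alpha


def centerline_points(params: VesselParams, t: np.ndarray | None = None) -> np.ndarray:
    """Analytic centerline (mm) evaluated at normalized stations ``t``."""
    if t is None:
        t = np.linspace(0.0, 1.0, params.n_stations)
    chord = _solve_chord(params)
    weights, dirs = _mode_basis(params.tortuosity_wavelengths, params.seed)
    alpha = params.tortuosity_amplitude / chord if chord > 0 else 0.0
    xy = _transverse_offsets(t, alpha, weights, dirs) * chord
    return np.column_stack([xy, chord * t])


def amplitude_for_tortuosity(
    target_index: float,
    target_actual_length: float,
    wavelengths: int = 2,
    seed: int = 0,
) -> float:
    """Transverse amplitude (mm) whose realized tortuosity index matches
    ``target_index`` (unit-chord arclength solved by root finding)."""
    if target_index < 1.0:
        raise ValueError("tortuosity index cannot be below 1")
    if target_index == 1.0:
        return 0.0
    weights, dirs = _mode_basis(wavelengths, seed)

    def g(alpha: float) -> float:
        return _unit_tortuosity(alpha, weights, dirs) - target_index

    lo, hi = 1e-9, 1.0
    while g(hi) < 0:
        hi *= 2.0
    alpha = brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)
    chord = target_actual_length / target_index
    return alpha * chord


def with_tortuosity(params: VesselParams, target_index: float) -> VesselParams:
    """Copy of ``params`` with the amplitude rescaled to hit ``target_index``."""
    amp = amplitude_for_tortuosity(
        target_index,
        params.target_actual_length,
        params.tortuosity_wavelengths,
        params.seed,
    )
    return dataclasses.replace(params, tortuosity_amplitude=amp)


# ---------------------------------------------------------------------------
# radius profile


def radius_profile(params: VesselParams, t: np.ndarray | float) -> np.ndarray:
    """Analytic radius (mm) at normalized arclength ``t``: geometric
    inlet-to-outlet interpolation times stenosis/aneurysm bump factors."""
    t = np.asarray(t, dtype=float)
    k = np.sqrt(params.outlet_inlet_area_ratio)  # outlet/inlet radius ratio
    r = params.inlet_radius * np.power(k, t)
    if params.stenosis is not None:
        st = params.stenosis
        r = r * (1.0 - st.severity * np.exp(-(((t - st.position) / st.width) ** 2)))
    if params.aneurysm is not None:
        an = params.aneurysm
        r = r * (1.0 + (an.bulge - 1.0) * np.exp(-(((t - an.position) / an.width) ** 2)))
    return r


# ---------------------------------------------------------------------------
# meshing


def _rmf_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing normal/binormal frames (double-reflection method)."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n = points.shape[0]
    normals = np.empty_like(points)
    helper = np.array([0.0, 1.0, 0.0])
    if abs(tangents[0] @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    n0 = np.cross(tangents[0], helper)
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = v1 @ v1
        rl = normals[i] - (2.0 / c1) * (v1 @ normals[i]) * v1
        tl = tangents[i] - (2.0 / c1) * (v1 @ tangents[i]) * v1
        v2 = tangents[i + 1] - tl
        c2 = v2 @ v2
        if c2 < 1e-30:
            normals[i + 1] = rl
        else:
            normals[i + 1] = rl - (2.0 / c2) * (v2 @ rl) * v2
        normals[i + 1] /= np.linalg.norm(normals[i + 1])
    binormals = np.cross(tangents, normals)
    return normals, binormals


def tube_mesh(
    centerline: np.ndarray, radius: np.ndarray, n_circumference: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight triangulated tube around ``centerline`` with per-station
    ``radius``; planar cap fans close the inlet and outlet.

    Returns ``(vertices, faces)`` with outward-oriented faces.
    """
    pts = np.asarray(centerline, dtype=float)
    r = np.asarray(radius, dtype=float)
    m, nc = pts.shape[0], n_circumference
    normals, binormals = _rmf_frames(pts)
    theta = np.linspace(0.0, 2.0 * np.pi, nc, endpoint=False)
    ring = (
        np.cos(theta)[None, :, None] * normals[:, None, :]
        + np.sin(theta)[None, :, None] * binormals[:, None, :]
    )
    verts = pts[:, None, :] + r[:, None, None] * ring
    verts = verts.reshape(m * nc, 3)
    # cap centers appended at the end
    verts = np.vstack([verts, pts[0], pts[-1]])
    c_in, c_out = m * nc, m * nc + 1

    faces = []
    for i in range(m - 1):
        for j in range(nc):
            a = i * nc + j
            b = i * nc + (j + 1) % nc
            c = (i + 1) * nc + j
            d = (i + 1) * nc + (j + 1) % nc
            faces.append((a, b, d))
            faces.append((a, d, c))
    for j in range(nc):  # inlet cap, normal pointing upstream
        faces.append((c_in, (j + 1) % nc, j))
    base = (m - 1) * nc
    for j in range(nc):  # outlet cap, normal pointing downstream
        faces.append((c_out, base + j, base + (j + 1) % nc))
    return verts, np.asarray(faces, dtype=np.int64)


def generate_vessel(params: VesselParams) -> VesselGeometry:
    """Build the watertight synthetic vein described by ``params``.

    The returned geometry carries the exact analytic centerline and radius
    profile at each station; the surface mesh discretizes the same tube.
    Identical parameters (including the seed) give bit-identical output.
    """
    from .geometry import mesh_is_watertight  # local to avoid cycle confusion

    t = np.linspace(0.0, 1.0, params.n_stations)
    pts = centerline_points(params, t)
    r = radius_profile(params, t)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seglen)])
    verts, faces = tube_mesh(pts, r, params.n_circumference)
    if not mesh_is_watertight(faces):
        raise RuntimeError("internal error: generated mesh is not watertight")
    return VesselGeometry(
        vertices=verts, faces=faces, centerline=pts, radius=r, arclength=arclength
    )


def semicircle_geometry(
    arc_radius: float = 20.0,
    tube_radius: float = 2.0,
    n_stations: int = 301,
    n_circumference: int = 32,
) -> VesselGeometry:
    """Preset: planar semicircular centerline (tortuosity index = pi/2)."""
    phi = np.linspace(0.0, np.pi, n_stations)
    pts = np.column_stack(
        [arc_radius * np.cos(phi), arc_radius * np.sin(phi), np.zeros(n_stations)]
    )
    r = np.full(n_stations, float(tube_radius))
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seglen)])
    verts, faces = tube_mesh(pts, r, n_circumference)
    return VesselGeometry(
        vertices=verts, faces=faces, centerline=pts, radius=r, arclength=arclength
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class DistSpec:
    """One marginal distribution: ``lognormal`` (median, log-sd), ``uniform``
    (low, high), ``normal`` (mean, sd) or ``constant`` (value, 0).

    Optional ``low``/``high`` truncate by resampling (deterministic given
    the generator state).
    """

    family: str
    a: float
    b: float = 0.0
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "uniform", "normal", "constant"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "lognormal" and self.a <= 0:
            raise ValueError("lognormal median must be positive")
        if self.family == "uniform" and self.b < self.a:
            raise ValueError("uniform bounds out of order")

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            if self.family == "lognormal":
                x = self.a * np.exp(self.b * rng.standard_normal())
            elif self.family == "uniform":
                x = rng.uniform(self.a, self.b)
            elif self.family == "normal":
                x = self.a + self.b * rng.standard_normal()
            else:
                x = self.a
            if (self.low is None or x >= self.low) and (
                self.high is None or x <= self.high
            ):
                return float(x)
        raise RuntimeError("truncated sampling failed after 1000 draws")

    def to_dict(self) -> dict:
        d = {"family": self.family, "a": self.a, "b": self.b}
        if self.low is not None:
            d["low"] = self.low
        if self.high is not None:
            d["high"] = self.high
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistSpec":
        return cls(
            family=d["family"],
            a=float(d["a"]),
            b=float(d.get("b", 0.0)),
            low=d.get("low"),
            high=d.get("high"),
        )


@dataclass(frozen=True)
class GroupConfig:
    """Per-group marginal distributions for every generative parameter."""

    inlet_area: DistSpec  # mm^2
    area_ratio: DistSpec
    actual_length: DistSpec  # mm
    tortuosity: DistSpec  # index >= 1
    inlet_velocity: DistSpec  # m/s
    p_stenosis: float = 0.0
    stenosis_severity: DistSpec = field(
        default_factory=lambda: DistSpec("uniform", 0.3, 0.6)
    )
    p_aneurysm: float = 0.0
    aneurysm_bulge: DistSpec = field(
        default_factory=lambda: DistSpec("uniform", 1.3, 1.8)
    )
    tortuosity_wavelengths: int = 2

    def __post_init__(self) -> None:
        for name in ("inlet_area", "area_ratio", "actual_length", "tortuosity"):
            spec: DistSpec = getattr(self, name)
            if spec.family == "lognormal" and spec.a <= 0:
                raise ValueError(f"{name}: median must be positive")
        if not 0.0 <= self.p_stenosis <= 1.0 or not 0.0 <= self.p_aneurysm <= 1.0:
            raise ValueError("lesion probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "inlet_area": self.inlet_area.to_dict(),
            "area_ratio": self.area_ratio.to_dict(),
            "actual_length": self.actual_length.to_dict(),
            "tortuosity": self.tortuosity.to_dict(),
            "inlet_velocity": self.inlet_velocity.to_dict(),
            "p_stenosis": self.p_stenosis,
            "stenosis_severity": self.stenosis_severity.to_dict(),
            "p_aneurysm": self.p_aneurysm,
            "aneurysm_bulge": self.aneurysm_bulge.to_dict(),
            "tortuosity_wavelengths": self.tortuosity_wavelengths,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupConfig":
        kw = {
            k: DistSpec.from_dict(d[k])
            for k in (
                "inlet_area",
                "area_ratio",
                "actual_length",
                "tortuosity",
                "inlet_velocity",
            )
        }
        for k in ("stenosis_severity", "aneurysm_bulge"):
            if k in d:
                kw[k] = DistSpec.from_dict(d[k])
        for k in ("p_stenosis", "p_aneurysm", "tortuosity_wavelengths"):
            if k in d:
                kw[k] = d[k]
        return cls(**kw)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: group sizes, per-group distributions, threshold, seed."""

    n_ruptured: int
    n_unruptured: int
    ruptured: GroupConfig
    unruptured: GroupConfig
    velocity_threshold: float = 0.113
    master_seed: int = 0
    n_stations: int = 301

    def __post_init__(self) -> None:
        if self.n_ruptured < 1 or self.n_unruptured < 1:
            raise ValueError("group sizes must be >= 1")
        if self.velocity_threshold <= 0:
            raise ValueError("velocity threshold must be positive")

    def to_dict(self) -> dict:
        return {
            "n_ruptured": self.n_ruptured,
            "n_unruptured": self.n_unruptured,
            "ruptured": self.ruptured.to_dict(),
            "unruptured": self.unruptured.to_dict(),
            "velocity_threshold": self.velocity_threshold,
            "master_seed": self.master_seed,
            "n_stations": self.n_stations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(
            n_ruptured=int(d["n_ruptured"]),
            n_unruptured=int(d["n_unruptured"]),
            ruptured=GroupConfig.from_dict(d["ruptured"]),
            unruptured=GroupConfig.from_dict(d["unruptured"]),
            velocity_threshold=float(d.get("velocity_threshold", 0.113)),
            master_seed=int(d.get("master_seed", 0)),
            n_stations=int(d.get("n_stations", 301)),
        )


def default_cohort_config(
    n_ruptured: int = 6, n_unruptured: int = 5, master_seed: int = 0
) -> CohortConfig:
    """Defaults emulating the emulated study's group medians: ruptured veins
    taper strongly (area ratio median 0.29) and carry faster inflow;
    unruptured veins are near-uniform (median 0.74) and slower."""
    ruptured = GroupConfig(
        inlet_area=DistSpec("lognormal", 22.87, 0.55, low=10.0, high=70.0),
        area_ratio=DistSpec("lognormal", 0.29, 0.22, low=0.18, high=0.55),
        actual_length=DistSpec("lognormal", 63.29, 0.18, low=36.0, high=80.0),
        tortuosity=DistSpec("lognormal", 1.50, 0.18, low=1.1, high=2.5),
        inlet_velocity=DistSpec("lognormal", 0.045, 0.35, low=0.015, high=0.15),
        p_stenosis=1.0 / 6.0,
        p_aneurysm=2.0 / 6.0,
    )
    unruptured = GroupConfig(
        inlet_area=DistSpec("lognormal", 29.86, 0.45, low=10.0, high=70.0),
        area_ratio=DistSpec("lognormal", 0.74, 0.45, low=0.35, high=1.30),
        actual_length=DistSpec("lognormal", 71.20, 0.15, low=36.0, high=80.0),
        tortuosity=DistSpec("lognormal", 2.06, 0.35, low=1.1, high=3.2),
        inlet_velocity=DistSpec("lognormal", 0.020, 0.45, low=0.005, high=0.08),
        p_stenosis=1.0 / 5.0,
        p_aneurysm=2.0 / 5.0,
    )
    return CohortConfig(
        n_ruptured=n_ruptured,
        n_unruptured=n_unruptured,
        ruptured=ruptured,
        unruptured=unruptured,
        master_seed=master_seed,
    )


def _draw_params(
    group: GroupConfig, rng: np.random.Generator, vessel_seed: int, n_stations: int
) -> VesselParams:
    inlet_area = group.inlet_area.sample(rng)
    ratio = group.area_ratio.sample(rng)
    length = group.actual_length.sample(rng)
    tort = max(group.tortuosity.sample(rng), 1.0)
    velocity = group.inlet_velocity.sample(rng)
    stenosis = None
    if rng.random() < group.p_stenosis:
        stenosis = Stenosis(
            position=rng.uniform(0.2, 0.8),
            severity=group.stenosis_severity.sample(rng),
        )
    aneurysm = None
    if rng.random() < group.p_aneurysm:
        aneurysm = Aneurysm(
            position=rng.uniform(0.2, 0.8),
            bulge=group.aneurysm_bulge.sample(rng),
        )
    base = VesselParams(
        inlet_radius=float(np.sqrt(inlet_area / np.pi)),
        outlet_inlet_area_ratio=ratio,
        target_actual_length=length,
        tortuosity_wavelengths=group.tortuosity_wavelengths,
        stenosis=stenosis,
        aneurysm=aneurysm,
        inlet_velocity=velocity,
        n_stations=n_stations,
        seed=vessel_seed,
    )
    return with_tortuosity(base, tort)


def generate_cohort(config: CohortConfig) -> list[tuple[VesselParams, bool]]:
    """Draw ``n_ruptured + n_unruptured`` parameter sets from the per-group
    distributions; child seeds derive deterministically from ``master_seed``.

    Returns ``[(params, ruptured_label), ...]`` with ruptured subjects first.
    """
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_ruptured + config.n_unruptured)
    out: list[tuple[VesselParams, bool]] = []
    for i, child in enumerate(children):
        ruptured = i < config.n_ruptured
        group = config.ruptured if ruptured else config.unruptured
        rng = np.random.default_rng(child)
        vessel_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        out.append((_draw_params(group, rng, vessel_seed, config.n_stations), ruptured))
    return out
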