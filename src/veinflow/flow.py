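"""Steady incompressible reduced-order flow along a vein.

The regime of interest is steady, rigid-wall, low-velocity tube flow, so
the solution is the quasi-1D fully developed laminar closure: a single
conserved flow rate, mean velocity ``Q/A(s)``, wall shear stress
``4*mu*Q/(pi*R(s)^3)`` and pressure integrated backward from the 0 Pa
outlet condition with ``dp/ds = -8*mu*Q/(pi*R(s)^4)``.  Every output is
analytically auditable.  All solver math is SI; geometry enters in mm and
is converted once at this boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VesselGeometry

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "FlowSolution",
    "velocity_from_transit",
    "poiseuille_wss",
    "poiseuille_pressure_gradient",
    "solve_steady_flow",
]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid."""

    density: float = 1066.0  # kg/m^3
    viscosity: float = 0.0035  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet mean velocity; fixed outlet pressure mimicking sinus pressure.

    ``pressure_report_offset`` is an additive reporting reference: tables
    quote ``gauge + offset`` so that a 0 Pa outlet field is reported on the
    ~1000 Pa scale; it never affects gradients or between-group differences.
    """

    inlet_mean_velocity: float
    outlet_pressure: float = 0.0
    pressure_report_offset: float = 1000.0

    def __post_init__(self) -> None:
        if self.inlet_mean_velocity < 0:
            raise ValueError("inlet mean velocity must be non-negative")
        if self.pressure_report_offset < 0:
            raise ValueError("pressure report offset must be non-negative")


@dataclass(frozen=True)
class FlowSolution:
    """Per-station steady solution fields (SI units, gauge pressure)."""

    flow_rate: float  # m^3/s, conserved
    arclength: np.ndarray  # m
    radius: np.ndarray  # m
    velocity: np.ndarray  # m/s, cross-section mean
    pressure: np.ndarray  # Pa gauge (outlet = outlet_pressure)
    wss: np.ndarray  # Pa
    reynolds_number: float
    pressure_report_offset: float = 0.0
    surface_wss: np.ndarray | None = None  # Pa per mesh face

    @property
    def reported_pressure(self) -> np.ndarray:
        """Gauge pressure shifted by the reporting offset."""
        return self.pressure + self.pressure_report_offset


def velocity_from_transit(roi_distance_mm: float, roi_time_s: float) -> float:
    """Transit velocity (m/s) from ROI path distance (mm) over transit time (s).

    This is the boundary-condition estimate used at the vein inlet.
    """
    if roi_time_s <= 0:
        raise ValueError("transit time must be positive")
    if roi_distance_mm < 0:
        raise ValueError("transit distance must be non-negative")
    return (roi_distance_mm * MM) / roi_time_s


def poiseuille_wss(flow_rate: float, radius: float, viscosity: float) -> float:
    """Fully developed laminar wall shear stress ``4*mu*Q/(pi*R^3)`` (Pa)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    return 4.0 * viscosity * flow_rate / (np.pi * radius**3)


def poiseuille_pressure_gradient(
    flow_rate: float, radius: float, viscosity: float
) -> float:
    """Magnitude of the laminar pressure gradient ``8*mu*Q/(pi*R^4)`` (Pa/m)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    return 8.0 * viscosity * flow_rate / (np.pi * radius**4)


def solve_steady_flow(
    geometry: VesselGeometry,
    bc: BoundaryConditions,
    fluid: FluidProperties = FluidProperties(),
    resistance_correction: Callable[[np.ndarray], np.ndarray] | None = None,
    map_surface_wss: bool = True,
) -> FlowSolution:
    """Solve the steady reduced-order problem on ``geometry``.

    Pressure is integrated from the outlet backward by the composite
    trapezoid rule, so on a uniform cylinder the result is exact.
    ``resistance_correction`` optionally multiplies the local pressure
    gradient by ``C(s_normalized)`` (default 1 everywhere); the hook exists
    for curvature/expansion losses but no correction is applied by default.
    """
    if geometry.n_stations < 2:
        raise ValueError("geometry must carry at least two stations")
    s = geometry.arclength * MM
    r = geometry.radius * MM
    if np.any(r <= 0):
        raise ValueError("all radii must be positive")

    area = np.pi * r**2
    q = bc.inlet_mean_velocity * area[0]
    velocity = q / area
    wss = 4.0 * fluid.viscosity * q / (np.pi * r**3)

    dpds = 8.0 * fluid.viscosity * q / (np.pi * r**4)
    if resistance_correction is not None:
        t = s / s[-1]
        corr = np.asarray(resistance_correction(t), dtype=float)
        if corr.shape != dpds.shape or np.any(corr <= 0):
            raise ValueError("resistance correction must be positive per station")
        dpds = dpds * corr

    # backward cumulative trapezoid from the outlet
    seg = np.diff(s)
    drops = 0.5 * (dpds[1:] + dpds[:-1]) * seg
    pressure = np.empty_like(s)
    pressure[-1] = bc.outlet_pressure
    pressure[:-1] = bc.outlet_pressure + np.cumsum(drops[::-1])[::-1]

    reynolds = fluid.density * bc.inlet_mean_velocity * 2.0 * r[0] / fluid.viscosity

    surface = None
    if map_surface_wss and geometry.faces.size:
        centroids = geometry.vertices[geometry.faces].mean(axis=1)
        tree = cKDTree(geometry.centerline)
        _, nearest = tree.query(centroids)
        surface = wss[nearest]

    return FlowSolution(
        flow_rate=float(q),
        arclength=s,
        radius=r,
        velocity=velocity,
        pressure=pressure,
        wss=wss,
        reynolds_number=float(reynolds),
        pressure_report_offset=bc.pressure_report_offset,
        surface_wss=surface,
    )
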