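"""Per-segment and per-subject aggregation of a flow solution.

Segment averages are arclength-weighted means over member stations;
subject-level averages are arclength-weighted means over all stations and
maxima are taken over stations (the finest available resolution).  A
segment is flagged "high velocity" when its mean velocity strictly
exceeds the threshold (default 0.113 m/s, the top of the velocity color
scale the flagging convention derives from).  Reported pressures include
the additive reporting offset carried by the solution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowSolution
from .geometry import (
    SegmentationScheme,
    VesselGeometry,
    absolute_length,
    actual_length,
    area_ratio,
    station_weights,
    tortuosity_index,
)

__all__ = [
    "SegmentSummary",
    "PatientSummary",
    "VeinRecord",
    "summarize_segments",
    "summarize_patient",
    "group_value",
    "group_segment_table",
    "build_vein_record",
]

DEFAULT_VELOCITY_THRESHOLD = 0.113  # m/s


@dataclass(frozen=True)
class SegmentSummary:
    segment_index: int  # 1..K
    group: str  # A | B | C
    pressure_avg: float  # Pa (reported scale)
    wss_avg: float  # Pa
    wss_max: float  # Pa
    velocity_avg: float  # m/s
    high_velocity: bool


@dataclass(frozen=True)
class PatientSummary:
    pressure_avg: float
    pressure_max: float
    wss_avg: float
    wss_max: float
    n_high_velocity: int


@dataclass(frozen=True)
class VeinRecord:
    """One subject: morphology, subject-level hemodynamics, segment detail."""

    subject_id: str
    ruptured: bool
    inlet_area: float  # mm^2
    exit_area: float  # mm^2
    area_ratio: float
    absolute_length: float  # mm
    actual_length: float  # mm
    tortuosity_index: float
    inlet_velocity: float  # m/s
    pressure_avg: float
    pressure_max: float
    wss_avg: float
    wss_max: float
    n_high_velocity: int
    segments: tuple[SegmentSummary, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.segments:
            if self.pressure_max < max(s.pressure_avg for s in self.segments) - 1e-9:
                raise ValueError("subject pressure_max below a segment average")
            if self.wss_max < max(s.wss_avg for s in self.segments) - 1e-9:
                raise ValueError("subject wss_max below a segment average")


def _group_of(scheme: SegmentationScheme, k: int) -> str:
    for label, members in scheme.groups.items():
        if k in members:
            return label
    raise ValueError(f"segment {k} not in any group")


def summarize_segments(
    solution: FlowSolution,
    scheme: SegmentationScheme,
    threshold: float = DEFAULT_VELOCITY_THRESHOLD,
) -> list[SegmentSummary]:
    """Arclength-weighted per-segment means (and WSS max) with the strict
    high-velocity flag ``velocity_avg > threshold``."""
    w = station_weights(solution.arclength)
    p = solution.reported_pressure
    out: list[SegmentSummary] = []
    for k in range(1, scheme.K + 1):
        idx = scheme.stations_in_segment(k)
        if idx.size == 0:
            raise ValueError(f"segment {k} has no stations")
        wk = w[idx]
        tot = wk.sum()
        v_avg = float((solution.velocity[idx] * wk).sum() / tot)
        # strict ">" with a 1e-12 relative guard against roundoff in the
        # weighted mean (a segment at exactly the threshold is not flagged)
        flagged = v_avg - threshold > 1e-12 * max(threshold, 1.0)
        out.append(
            SegmentSummary(
                segment_index=k,
                group=_group_of(scheme, k),
                pressure_avg=float((p[idx] * wk).sum() / tot),
                wss_avg=float((solution.wss[idx] * wk).sum() / tot),
                wss_max=float(solution.wss[idx].max()),
                velocity_avg=v_avg,
                high_velocity=bool(flagged),
            )
        )
    return out


def summarize_patient(
    solution: FlowSolution, segments: list[SegmentSummary]
) -> PatientSummary:
    """Subject-level aggregate: station-weighted averages, station maxima,
    and the count of high-velocity segments."""
    if not segments:
        raise ValueError("need at least one segment summary")
    w = station_weights(solution.arclength)
    p = solution.reported_pressure
    tot = w.sum()
    return PatientSummary(
        pressure_avg=float((p * w).sum() / tot),
        pressure_max=float(p.max()),
        wss_avg=float((solution.wss * w).sum() / tot),
        wss_max=float(solution.wss.max()),
        n_high_velocity=int(sum(s.high_velocity for s in segments)),
    )


_QUANTITIES = {"pressure": "pressure_avg", "wss": "wss_avg", "velocity": "velocity_avg"}


def group_value(record: VeinRecord, group: str, quantity: str) -> float:
    """Subject-level mean of ``quantity`` over one segment group (A/B/C).

    Segments have equal arclength, so the group value is the plain mean of
    the member segment averages.
    """
    if group not in ("A", "B", "C"):
        raise ValueError(f"unknown group label {group!r}")
    if quantity not in _QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; use {sorted(_QUANTITIES)}")
    attr = _QUANTITIES[quantity]
    members = [s for s in record.segments if s.group == group]
    if not members:
        raise ValueError(f"record {record.subject_id} has no group-{group} segments")
    return float(np.mean([getattr(s, attr) for s in members]))


def group_segment_table(
    records: list[VeinRecord], group: str, quantity: str
) -> np.ndarray:
    """Per-subject group-level values, one entry per record."""
    return np.array([group_value(r, group, quantity) for r in records])


def build_vein_record(
    subject_id: str,
    ruptured: bool,
    geometry: VesselGeometry,
    solution: FlowSolution,
    scheme: SegmentationScheme,
    threshold: float = DEFAULT_VELOCITY_THRESHOLD,
) -> VeinRecord:
    """Assemble morphology + hemodynamics for one subject."""
    segments = summarize_segments(solution, scheme, threshold)
    patient = summarize_patient(solution, segments)
    act = actual_length(geometry)
    absl = absolute_length(geometry)
    return VeinRecord(
        subject_id=subject_id,
        ruptured=ruptured,
        inlet_area=geometry.inlet_area,
        exit_area=geometry.exit_area,
        area_ratio=area_ratio(geometry.exit_area, geometry.inlet_area),
        absolute_length=absl,
        actual_length=act,
        tortuosity_index=tortuosity_index(act, absl),
        inlet_velocity=float(solution.velocity[0]),
        pressure_avg=patient.pressure_avg,
        pressure_max=patient.pressure_max,
        wss_avg=patient.wss_avg,
        wss_max=patient.wss_max,
        n_high_velocity=patient.n_high_velocity,
        segments=tuple(segments),
    )
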