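"""End-to-end cohort pipeline: generate -> solve -> summarize -> stats.

The whole run is a pure function of (config, seed): geometry, solution and
summary files are written per subject, then cohort tables, trend plots and
a checksum manifest.  ``import_vein`` is the entry point for externally
supplied geometries (STL + centerline CSV).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .flow import BoundaryConditions, FluidProperties, solve_steady_flow
from .geometry import VesselGeometry, divide_segments, mesh_is_watertight
from .io import (
    read_centerline_csv,
    read_stl,
    write_centerline_csv,
    write_manifest,
    write_segmentation_csv,
    write_solution_csv,
    write_stl,
    write_vtk_surface,
)
from .stats import (
    COMPARABLE_VARIABLES,
    GroupComparison,
    StatResult,
    compare_groups,
    high_velocity_contingency,
    mann_whitney,
    pearson_trend,
    pooled_segment_values,
    spearman_trend,
)
from .summary import VeinRecord, build_vein_record
from .synthetic import CohortConfig, default_cohort_config, generate_cohort, generate_vessel

log = logging.getLogger("veinflow")

__all__ = ["PipelineConfig", "run_pipeline", "import_vein", "cohort_records", "records_to_frame"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig
    k_segments: int = 15
    velocity_threshold: float = 0.113  # m/s
    fluid: FluidProperties = field(default_factory=FluidProperties)
    outlet_pressure: float = 0.0  # Pa
    pressure_report_offset: float = 1000.0  # Pa
    mw_method: str = "auto"  # mann-whitney: auto | exact | asymptotic
    write_geometry: bool = True
    write_plots: bool = True

    def __post_init__(self) -> None:
        if self.k_segments < 1:
            raise ValueError("k_segments must be >= 1")
        if self.velocity_threshold <= 0:
            raise ValueError("velocity threshold must be positive")
        if self.pressure_report_offset < 0:
            raise ValueError("pressure report offset must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a YAML mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {
            "cohort",
            "k_segments",
            "velocity_threshold",
            "fluid",
            "outlet_pressure",
            "pressure_report_offset",
            "mw_method",
            "write_geometry",
            "write_plots",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cohort = (
            CohortConfig.from_dict(raw["cohort"]) if "cohort" in raw else default_cohort_config()
        )
        fluid = FluidProperties(**raw.get("fluid", {}))
        kw = {k: raw[k] for k in known - {"cohort", "fluid"} if k in raw}
        return cls(cohort=cohort, fluid=fluid, **kw)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "k_segments": self.k_segments,
            "velocity_threshold": self.velocity_threshold,
            "fluid": {"density": self.fluid.density, "viscosity": self.fluid.viscosity},
            "outlet_pressure": self.outlet_pressure,
            "pressure_report_offset": self.pressure_report_offset,
            "mw_method": self.mw_method,
        }


def _analyze_vein(
    subject_id: str,
    ruptured: bool,
    geometry: VesselGeometry,
    inlet_velocity: float,
    config: PipelineConfig,
) -> tuple[VeinRecord, "object", "object"]:
    bc = BoundaryConditions(
        inlet_mean_velocity=inlet_velocity,
        outlet_pressure=config.outlet_pressure,
        pressure_report_offset=config.pressure_report_offset,
    )
    scheme = divide_segments(geometry, config.k_segments)
    solution = solve_steady_flow(geometry, bc, config.fluid)
    record = build_vein_record(
        subject_id, ruptured, geometry, solution, scheme, config.velocity_threshold
    )
    return record, solution, scheme


def cohort_records(config: PipelineConfig, seed: int | None = None) -> list[VeinRecord]:
    """Generate and analyze the synthetic cohort in memory (no files)."""
    cohort = config.cohort
    if seed is not None:
        cohort = dataclasses.replace(cohort, master_seed=seed)
    records = []
    for i, (params, ruptured) in enumerate(generate_cohort(cohort)):
        label = "R" if ruptured else "U"
        geometry = generate_vessel(params)
        record, _, _ = _analyze_vein(
            f"{label}{i:02d}", ruptured, geometry, params.inlet_velocity, config
        )
        records.append(record)
    return records


def records_to_frame(records: Sequence[VeinRecord]) -> pd.DataFrame:
    """Tidy table: one row per subject (kind='subject') and one per
    subject-segment (kind='segment')."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        segs = d.pop("segments")
        d["kind"] = "subject"
        rows.append(d)
        for s in segs:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "ruptured": r.ruptured,
                    "kind": "segment",
                    **s,
                }
            )
    return pd.DataFrame(rows)


def _stat_to_dict(res: StatResult) -> dict:
    d = dataclasses.asdict(res)
    d.pop("extra", None)
    d.update(res.extra)
    return d


def cohort_statistics(records: Sequence[VeinRecord], mw_method: str = "auto") -> dict:
    """All cohort-level tests: group comparisons, pooled segment trends and
    the two readings of the high-velocity analysis (per-segment contingency
    and per-subject rank-sum on flag counts)."""
    comparisons: dict[str, GroupComparison] = {}
    for var in COMPARABLE_VARIABLES:
        comparisons[var] = compare_groups(records, var, method=mw_method)

    trends: dict[str, dict] = {}
    for quantity in ("pressure", "wss", "velocity"):
        for ruptured, label in ((True, "ruptured"), (False, "unruptured")):
            x, y = pooled_segment_values(records, quantity, ruptured)
            trends[f"{quantity}_{label}"] = {
                "spearman": _stat_to_dict(spearman_trend(x, y)),
                "pearson": _stat_to_dict(pearson_trend(x, y)),
                "n_points": int(x.size),
            }

    k = len(records[0].segments)
    flagged_r = sum(r.n_high_velocity for r in records if r.ruptured)
    total_r = k * sum(1 for r in records if r.ruptured)
    flagged_u = sum(r.n_high_velocity for r in records if not r.ruptured)
    total_u = k * sum(1 for r in records if not r.ruptured)
    contingency = high_velocity_contingency(flagged_r, total_r, flagged_u, total_u)
    fisher = high_velocity_contingency(
        flagged_r, total_r, flagged_u, total_u, method="fisher"
    )
    per_patient = mann_whitney(
        [r.n_high_velocity for r in records if r.ruptured],
        [r.n_high_velocity for r in records if not r.ruptured],
        method=mw_method,
    )
    return {
        "comparisons": comparisons,
        "trends": trends,
        "high_velocity": {
            "chi2_segments": _stat_to_dict(contingency),
            "fisher_segments": _stat_to_dict(fisher),
            "mann_whitney_counts": _stat_to_dict(per_patient),
        },
    }


def _comparison_tables(stats: dict) -> tuple[pd.DataFrame, str]:
    rows = []
    for var, comp in stats["comparisons"].items():
        rows.append(
            {
                "variable": var,
                "ruptured_median": comp.median_a,
                "ruptured_q1": comp.q1_a,
                "ruptured_q3": comp.q3_a,
                "unruptured_median": comp.median_b,
                "unruptured_q1": comp.q1_b,
                "unruptured_q3": comp.q3_b,
                "test": comp.test.test_name,
                "p_value": comp.test.p_value,
            }
        )
    df = pd.DataFrame(rows)
    md_lines = [
        "| Variable | Ruptured median [IQR] | Unruptured median [IQR] | p |",
        "| --- | --- | --- | --- |",
    ]
    for _, r in df.iterrows():
        md_lines.append(
            f"| {r['variable']} "
            f"| {r['ruptured_median']:.3g} [{r['ruptured_q1']:.3g}, {r['ruptured_q3']:.3g}] "
            f"| {r['unruptured_median']:.3g} [{r['unruptured_q1']:.3g}, {r['unruptured_q3']:.3g}] "
            f"| {r['p_value']:.4g} |"
        )
    hv = stats["high_velocity"]["chi2_segments"]
    md_lines.append(
        f"| high_velocity_segments | {hv['percent_a']}% | {hv['percent_b']}% "
        f"| {hv['p_value']:.4g} |"
    )
    md_lines.append("")
    md_lines.append("| Trend (pooled) | Spearman rho | p | Pearson R |")
    md_lines.append("| --- | --- | --- | --- |")
    for key, tr in stats["trends"].items():
        md_lines.append(
            f"| {key} | {tr['spearman']['statistic']:.3f} "
            f"| {tr['spearman']['p_value']:.4g} | {tr['pearson']['statistic']:.3f} |"
        )
    return df, "\n".join(md_lines) + "\n"


def _trend_plots(records: Sequence[VeinRecord], outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    labels = {"wss": "WSS (Pa)", "pressure": "Pressure (Pa)", "velocity": "Velocity (m/s)"}
    for quantity, ylabel in labels.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, (ruptured, title) in zip(
            axes, ((True, "ruptured"), (False, "unruptured"))
        ):
            x, y = pooled_segment_values(records, quantity, ruptured)
            ax.scatter(x, y, s=12, alpha=0.6)
            if np.ptp(y) > 0:
                coef = np.polyfit(x, y, 1)
                xs = np.array([x.min(), x.max()])
                ax.plot(xs, np.polyval(coef, xs), "r-", lw=1)
                r = pearson_trend(x, y)
                ax.set_title(f"{title}  R={r.statistic:.3f}")
            else:
                ax.set_title(title)
            ax.set_xlabel("segment index")
        axes[0].set_ylabel(ylabel)
        fig.tight_layout()
        path = outdir / f"trend_{quantity}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the full cohort analysis; returns the statistics bundle.

    Writes, under ``outdir``: per-subject geometry (STL + centerline CSV),
    solution CSV, segmentation CSV and VTK surface; cohort ``records.csv``/
    ``records.json``; ``stats.csv``/``stats.md``; trend plots; and
    ``manifest.json`` with sha256 checksums of the text outputs.
    """
    t0 = time.monotonic()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort
    if seed is not None:
        cohort = dataclasses.replace(cohort, master_seed=seed)
        config = dataclasses.replace(config, cohort=cohort)

    records: list[VeinRecord] = []
    text_outputs: list[Path] = []
    for i, (params, ruptured) in enumerate(generate_cohort(cohort)):
        label = "R" if ruptured else "U"
        sid = f"{label}{i:02d}"
        geometry = generate_vessel(params)
        record, solution, scheme = _analyze_vein(
            sid, ruptured, geometry, params.inlet_velocity, config
        )
        records.append(record)
        vdir = out / "veins" / sid
        vdir.mkdir(parents=True, exist_ok=True)
        if config.write_geometry:
            write_stl(vdir / "surface.stl", geometry.vertices, geometry.faces)
            write_vtk_surface(vdir / "surface_wss.vtk", geometry, solution.surface_wss)
        write_centerline_csv(vdir / "centerline.csv", geometry)
        write_solution_csv(vdir / "solution.csv", geometry, solution)
        write_segmentation_csv(vdir / "segments.csv", scheme)
        text_outputs += [vdir / "centerline.csv", vdir / "solution.csv", vdir / "segments.csv"]
        log.info("solved %s (ruptured=%s, %d stations)", sid, ruptured, geometry.n_stations)

    frame = records_to_frame(records)
    frame.to_csv(out / "records.csv", index=False)
    (out / "records.json").write_text(
        json.dumps([dataclasses.asdict(r) for r in records], indent=1, sort_keys=True) + "\n"
    )
    stats = cohort_statistics(records, mw_method=config.mw_method)
    df, md = _comparison_tables(stats)
    df.to_csv(out / "stats.csv", index=False)
    (out / "stats.md").write_text(md)
    (out / "trends.json").write_text(
        json.dumps(
            {"trends": stats["trends"], "high_velocity": stats["high_velocity"]},
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    text_outputs += [
        out / "records.csv",
        out / "records.json",
        out / "stats.csv",
        out / "stats.md",
        out / "trends.json",
    ]
    if config.write_plots:
        plots = out / "plots"
        plots.mkdir(exist_ok=True)
        _trend_plots(records, plots)
    write_manifest(
        out / "manifest.json",
        seed=cohort.master_seed,
        config=config.to_dict(),
        files=text_outputs,
        root=out,
    )
    log.info("pipeline finished in %.1f s (%d subjects)", time.monotonic() - t0, len(records))
    return {"records": records, "statistics": stats}


def import_vein(
    stl_path: str | Path,
    centerline_csv: str | Path,
    bc: BoundaryConditions,
    fluid: FluidProperties = FluidProperties(),
    K: int = 15,
    velocity_threshold: float = 0.113,
    subject_id: str = "imported",
    ruptured: bool = False,
) -> VeinRecord:
    """Analyze an externally supplied vein (STL + centerline CSV)."""
    verts, faces = read_stl(stl_path)
    if not mesh_is_watertight(faces):
        raise ValueError(f"mesh {stl_path} is not watertight")
    pts, s, radius = read_centerline_csv(centerline_csv)
    if pts.shape[0] < K:
        raise ValueError(
            f"insufficient stations: {pts.shape[0]} stations cannot fill K={K} segments"
        )
    if np.any(radius < 0.1) or np.any(radius > 20.0):
        log.warning(
            "radii outside 0.1-20 mm in %s: check that units are millimetres",
            centerline_csv,
        )
    geometry = VesselGeometry(
        vertices=verts, faces=faces, centerline=pts, radius=radius, arclength=s
    )
    scheme = divide_segments(geometry, K)
    solution = solve_steady_flow(geometry, bc, fluid)
    return build_vein_record(
        subject_id, ruptured, geometry, solution, scheme, velocity_threshold
    )
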