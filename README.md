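# veinflow

Reduced-order hemodynamics of cerebral AVM draining veins.

The package builds an end-to-end, fully deterministic analysis pipeline:

1. **`veinflow.synthetic`** — parametric generation of watertight tubular
   vein geometries (seeded sinusoidal centerlines, geometric inlet→outlet
   radius interpolation, optional stenosis/aneurysm bumps) and of two-group
   cohorts ("ruptured-like": strong distal taper, faster inflow;
   "unruptured-like": near-uniform caliber, slower inflow).
2. **`veinflow.geometry`** — centerline arclength handling, morphology
   metrics (tortuosity index = actual/absolute length, outlet/inlet area
   ratio), division into K = 15 equal-arclength segments with A/B/C
   grouping (segments 1–5 / 6–10 / 11–15), and mesh audits (watertightness,
   cross-section slicing, cap areas).
3. **`veinflow.flow`** — steady incompressible quasi-1D flow with blood
   properties ρ = 1066 kg/m³, μ = 0.0035 Pa·s, an inlet mean-velocity
   boundary condition and a 0 Pa outlet: conserved flow rate, mean velocity
   Q/A(s), wall shear stress 4μQ/(πR³), pressure integrated backward from
   the outlet with dp/ds = −8μQ/(πR⁴). Reported pressures add a
   configurable +1000 Pa reference offset (gradients are unaffected).
4. **`veinflow.summary`** — per-segment and per-subject aggregates,
   including the strict high-velocity flag (segment mean velocity
   \> 0.113 m/s).
5. **`veinflow.stats`** — Mann–Whitney U (exact for small tie-free samples),
   Spearman/Pearson segment-trend correlations pooled across subjects,
   Pearson chi-squared (and Fisher exact) on the high-velocity 2×2 segment
   table, and median [IQR] group comparison tables.
6. **`veinflow.pipeline` / `veinflow.cli`** — the reproducible end-to-end
   run with manifest checksums, plus import of externally supplied
   geometries (STL + centerline CSV).

## CLI

```bash
# full synthetic-cohort analysis (geometries, solutions, stats, plots, manifest)
veinflow run-all --out out/ --seed 1

# stages
veinflow generate --out geoms/ --seed 1
veinflow solve --stl geoms/R00/surface.stl --centerline geoms/R00/centerline.csv \
    --inlet-velocity 0.05 --out sol/
veinflow summarize --stl geoms/R00/surface.stl --centerline geoms/R00/centerline.csv \
    --inlet-velocity 0.05 --out record.json
veinflow stats --records out/records.json --out stats/
```

Useful flags: `--k-segments`, `--velocity-threshold`, `--pressure-offset`,
`--exact-mw/--approx-mw`, `--config <yaml>` (see
`PipelineConfig.from_yaml`; `PipelineConfig(...).to_dict()` round-trips).

### Output schemas

* `centerline.csv`: `station_index, x_mm, y_mm, z_mm, arclength_mm, radius_mm`
* `solution.csv`: `s_mm, radius_mm, velocity_mps, pressure_pa, wss_pa`
  (pressure on the reported scale, i.e. gauge + offset)
* `segments.csv`: `segment_index, s_start_mm, s_end_mm, group`
* `records.csv`: tidy — one `kind="subject"` row per vein (morphology +
  subject-level hemodynamics) and one `kind="segment"` row per
  vein-segment
* `surface.stl` (binary), `surface_wss.vtk` (legacy ASCII VTK with a
  per-face WSS scalar), `manifest.json` (seeds, config, sha256 checksums
  of all text outputs — identical config + seed ⇒ identical checksums)

## Units

Geometry files are in millimetres; all solver math is SI (metres, Pa,
m/s); conversion happens once at the solver boundary. Velocities are in
m/s and pressures in Pa throughout the reports.
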