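# drydown

Analysis toolkit for dual-technique hydraulic-vulnerability experiments on
bench-dehydrated seedlings:

- **Acoustic emissions (AE)** — per-minute acoustic activity, Savitzky–Golay
  smoothing, and the water potential at the main activity peak (the
  50 %-embolism proxy), per individual and per group.
- **Optical visualization (OV)** — successive-frame differencing of a
  drydown image stack, connected-component embolism events with union-mask
  deduplication, and the percent-embolized-area series
  (`100 · A_cum / A_max`).
- **Weibull vulnerability curves** — least-squares fits of embolized
  fraction vs water potential, 12 / 50 / 88 % thresholds, bootstrap and
  SSR-profile 95 % confidence intervals, and closed-form quantile algebra
  including a two-quantile solver.
- **Water-potential timelines** — per-timepoint averaging of pressure-chamber
  readings and exact linear interpolation.
- **Anatomy metrics** — conduit diameters from lumen areas (circle/square
  models), hierarchical means, hydraulic diameter `Σd⁵/Σd⁴`, wall
  reinforcement `(t/b)²` with the `d_h ± 1 µm` selection rule, 1-µm diameter
  class histograms, and xylem geometry.
- **Statistics** — ΔΨ between techniques, one-way ANOVA + Tukey HSD with a
  compact letter display, CI-overlap comparisons, Pearson trait–threshold
  correlation matrices.
- **Synthetic drydown simulator** — conduit populations with Weibull
  air-seeding thresholds, optional sub-resolution small-conduit classes with
  a resistance shift, AE streams with a non-plateauing nuisance process, OV
  image stacks, and noisy pressure-chamber sampling — all seeded and carrying
  their ground truth for parameter-recovery tests.

## CLI

```bash
# synthetic dataset (ae.csv, psi.csv, frames/ + manifest.csv, truth.json)
drydown simulate --out ds --seed 1 --n-conduits 300 --duration 7200 --psi-end -7

# run every available branch (AE, OV + curve fit, technique delta)
drydown analyze --dataset ds --out results

# individual stages
drydown ae  --ae-csv ds/ae.csv --psi-csv ds/psi.csv --out results/ae
drydown ov  --stack-dir ds --psi-csv ds/psi.csv --out results/ov
drydown fit --ov-csv results/ov/ov_series.csv --out results/fit \
    --ci-method bootstrap --resample residual   # residual suits fixed psi schedules
drydown anatomy --conduits-csv conduits.csv --walls-csv walls.csv --out results/anatomy
drydown compare --groups-csv groups.csv --out results/compare
drydown quantile-solve -- -1.60 -2.24   # curve through 12%/88% -> psi50
```

Each command writes a `run_log.json` provenance record (parameters, seeds,
package version) next to its outputs.

## Data formats

CSV with comma separators, dot decimals, and a header row:

| file | columns |
|---|---|
| AE log | `time_s,amplitude_db,plant_id` |
| psi readings | `time_s,psi_mpa,plant_id` |
| stack manifest | `frame,filename,time_s` (frames: grayscale TIFF/PNG) |
| conduits | `sample_id,lumen_area_um2,shape` |
| wall pairs | `sample_id,t_um,span_um` |
| group table | `group,value` |

All water potentials are stored signed-negative (MPa); tension appears only
inside the Weibull algebra.
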