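# necroscope

Quantitative phase-imaging pipeline for distinguishing apoptosis from
oncosis in time-lapse microscopy, with a flow-cytometry cross-check.

The package covers the full analysis loop on synthetic data:

- **phantoms** — synthetic cell phase maps with known dry mass and one of
  three fates (swelling with membrane blebs, shrinkage with late
  fragmentation into bodies, or no change), ideal two-beam off-axis
  hologram rendering, and class-conditional flow-cytometry event
  simulation (viable / apoptotic / oncotic / necrotic / debris).
- **recon** — numerical reconstruction: carrier estimation, Fourier
  sideband demodulation, quality-guided phase unwrapping, first-order
  background flattening, simulated DIC display.
- **quant** — phase-to-dry-mass conversion (default 0.21 rad ≙ 0.05
  pg/pixel), threshold segmentation, marker-seeded watershed separation of
  touching cells, per-cell area / dry mass / mean density.
- **track** — greedy mutual-nearest-centroid linking, size-trajectory
  classification (increase / decrease / no change), cohort statistics
  (class fractions, mass-stability fraction, decrease-vs-rest mass ratio).
- **cyto** — annexin V / PI quadrant gating from an unstained control,
  FSC back-gating of the annexin+/PI− quadrant into smaller (R1) and
  larger (R2) sub-populations, size-class mapping (plain and adjusted for
  oncosis), Pearson chi-squared contingency comparison.
- **staging** — rule-based oncosis progression staging (transition /
  early / late / necrosis-transition) from morphological and staining
  features.
- **cli** — `necroscope` with subcommands `simulate`, `reconstruct`,
  `quantify`, `classify`, `fcm-gate`, `compare`, `stage`, `run`.

## CLI quick start

```sh
cat > config.yaml <<EOF
seed: 1
simulate: {image_shape: [512, 512], cell_count: 30, n_frames: 20}
fcm:
  n_events: 10000
  class_mix: {viable: 0.55, apoptotic: 0.0951, oncotic: 0.1322, necrotic: 0.0775, debris: 0.1452}
EOF
necroscope run --config config.yaml --out out/
```

`out/summary.yaml` holds the class fractions and mass statistics;
`out/contingency.yaml` the morphology-vs-cytometry chi-squared table.
Stages can also be run one at a time via plain-file handoff
(TIFF / CSV / YAML), e.g.:

```sh
necroscope simulate --config config.yaml --out out/
necroscope reconstruct --in out/holograms.tif --out out/phase.tif
necroscope quantify --phase out/phase.tif --out out/cells.csv
necroscope classify --cells out/cells.csv --out out/summary.yaml
```

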