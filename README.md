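# tjquant

Quantification pipeline for 2D single-molecule localization microscopy
(SMLM/dSTORM) point patterns of endothelial tight-junction proteins:

- **io** — ThunderSTORM-style molecular-list CSV reader/writer (dialect
  driven, units inferred from bracketed header suffixes), JSON capillary-ROI
  annotations, and mass-conserving QC rendering (histogram / Gaussian).
- **clustering** — strict distance-threshold single-linkage partitioning
  (default 70 nm; two points cluster iff chained by pairwise distances
  *strictly below* the threshold), convex-hull cluster area (µm²), density
  (signals/µm²), threshold sweeps and distribution summaries.
- **capillary** — total cellular signal per capillary cross-section,
  diameter estimation (moment-matched ellipse, equivalent circle, max
  Feret), diameter-normalized abundance (signals/µm), and cluster-coupling
  classification between two channels (coupled iff minimum member-to-member
  distance ≤ 100 nm by default).
- **leakage** — abluminal band construction by outward polygon offsets
  (defaults 100–300 nm), tracer density in the band, and the relative
  leakage index normalized so the reference group's mean index is exactly 1.
- **stats** — two-tailed Mann–Whitney U (exact for small tie-free samples,
  tie-corrected normal approximation otherwise) and Kruskal–Wallis plus
  Dunn's post-hoc tests with Bonferroni/Holm adjustment.
- **synthetic** — Neyman–Scott-style scene generator with full ground truth
  (molecule→blink lineage, planted memberships, tracer classes), explicit
  blinking/overcounting amplification, hard-core cluster spacing for
  well-separated regimes, and planted-parameter recovery reports.
- **cli** — `tjquant` command with `simulate`, `cluster`, `capillary`,
  `couple`, `leakage` and `compare` subcommands; every run writes its fully
  resolved parameters to `run_config.json` beside the outputs and logs to
  stderr + `run.log`.

## CLI quick start

```sh
tjquant simulate --preset P9-like --seed 1 --out out/sim
tjquant cluster out/sim/claudin5.csv --threshold-nm 70 --out out/clu
tjquant capillary out/sim/claudin5.csv out/sim/ring_roi.json --out out/cap
tjquant couple claudin5.csv zo1.csv --pairing-nm 100 --out out/coup
tjquant leakage --manifest manifest.csv --band-nm 100:300 \
    --reference-group P9 --out out/leak
tjquant compare tidy.csv --out out/cmp
```

The leakage manifest is a CSV with columns
`capillary_id,group,tracer_csv,ring_roi`.

## File formats

- Molecular list CSV: `"x [nm]","y [nm]","frame","intensity [photon]","uncertainty [nm]"`
  (dialect configurable; µm columns converted on read).
- ROI JSON: `{"label": "...", "vertices_nm": [[x, y], ...]}` — a simple
  closed polygon in nm, ≥ 3 vertices, self-intersections rejected.

All internal computation is in nanometres (x rightward, y downward); areas
are reported in µm², densities in signals/µm².
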