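# awfc — anatomically weighted functional connectivity

`awfc` fuses structural and functional brain connectivity at the ROI-pair
level and tests for group differences:

1. **Structural stage** — tractography streamline summaries are converted to
   connection probabilities (90th percentile of voxel-level counts divided by
   streamlines leaving the source ROI), corrected for distance bias with a
   zero-inflated Poisson regression (`log μ = α0 + α1·g`), and augmented with
   second-order (one-intermediate) connections via
   `π_ij = max[π_ij, max_m(π_im·π_mj)]`.
2. **Fusion** — structural and functional dissimilarities are multiplied,
   `awFd = (1−SC)·(1−FC)`, and mapped back to a connectivity scale,
   `awFC = 1 − |awFd|`.
3. **Group statistics** — per within-network ROI pair, two-sample Wilcoxon
   tests on SC, FC and awFC (exact null distribution for small tie-free
   samples), Benjamini–Hochberg FDR per metric, and Cohen's d with
   negligible/small/medium/large labels.

A synthetic-cohort generator (block-correlated ROI time series plus
distance-dependent zero-inflated Poisson streamline counts, with optional
planted group effects) stands in for MRI-derived inputs, so the whole
pipeline is testable offline. The packaged default atlas has 19 ROIs in
5 resting-state networks (DMN, FPN, LIM, VAN, DAN).

## CLI

```sh
# generate a synthetic cohort (manifest + per-subject TSVs)
awfc simulate --out cohort/ --seed 42

# full pipeline: QC -> grouping -> SC stage -> fusion -> statistics -> report
awfc run --manifest cohort/manifest.tsv --out results/ --seed 42

# individual stages
awfc sc --counts s1_counts.tsv --totals s1_totals.tsv --grid s1_grid.tsv \
        --out s1_sc.tsv --percentile 90 --adjust median-distance --second-order
awfc fuse --sc s1_sc.tsv --fc s1_fc.tsv --out s1_awfc.tsv
```

`awfc run` writes `group_stats.tsv` (one row per ROI pair: raw and
FDR-adjusted p-values for SC/FC/awFC, Cohen's d and size label), per-subject
awFC tables, a `summary.json` run report, and boxplots for significant pairs
(`*` q < 0.05, `**` q < 0.01). Options (QC threshold 0.55 mm, percentile,
adjustment mode, symmetrization, second-order toggle, FDR scope, thresholds)
can be set in a YAML config passed via `--config`; a `sim:` section replaces
`--manifest` with a simulated cohort. Exit codes: 0 success, 2 validation
error, 3 computation error.

## Input formats

- **Labeled matrices** (FC, distances, SC): TSV with a label header row and
  label first column, or whitespace-delimited grid text with `#` comments
  and a label line.
- **Voxel counts**: long TSV `source_roi  target_roi  voxel_index  count`,
  plus a totals TSV `roi  total_leaving`.
- **Manifest**: TSV/CSV with `subject_id`, `mean_relative_displacement`,
  adversity questionnaire scores (`epds`, `stai`, `ham_a`, `madrs`,
  `low_income`) and/or an explicit `group`, and per-subject file references
  (`fc_path`, `counts_path`, `totals_path`, `grid_path`).

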