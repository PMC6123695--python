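# replimap

Split-half pseudo-replicate replicability analysis for volumetric
statistical maps (task-fMRI style), driven by a synthetic multi-subject
dataset generator.

Given per-subject contrast maps, the pipeline repeatedly splits the sample
into disjoint same-size halves ("P" and "Q"), builds group z maps for nested
sample sizes `k`, and quantifies how well the paired maps replicate at three
levels of granularity:

* **voxel (intensity)** — Pearson correlation of the unthresholded maps;
* **voxel (thresholded)** — sign-sensitive Jaccard overlap after two-tailed
  proportion thresholding matched to the full-sample suprathreshold
  proportion;
* **cluster / peak** — sign-sensitive Jaccard and peak hit rates after
  two-tailed Gaussian-random-field cluster-extent thresholding.

Each observed curve is paired with a smoothness-matched null curve built
from smoothed-noise maps whose FWHM and robust intensity range are sampled
from normal fits to the real maps' statistics (95th percentile per map,
averaged across maps). A "measurables" regression then explains pair-level
replicability from motion, design contrast power, hat-matrix leverage
outliers, within- and between-subject map similarity, and sample size, with
per-task effect sizes and ΔR² aggregated across tasks by MAP shrinkage.

## Layout

| module | contents |
| --- | --- |
| `replimap.statmap` | `StatMap` / `GroupMap` containers, NIfTI I/O |
| `replimap.synthetic` | truth maps, random-field subject/run simulation, double-gamma HRF designs, dataset round-trip |
| `replimap.groupmodel` | subject-level run averaging, one-sample t→z group maps, common masks |
| `replimap.resampling` | split plans (repeated disjoint P/Q sorts with nested k prefixes) |
| `replimap.thresholding` | FWHM estimation, proportion & GRF cluster thresholding, signed components, peaks, threshold scaling rule |
| `replimap.similarity` | Pearson / signed Jaccard / peak hit rate, peak-height logistic fit |
| `replimap.nulls` | null model fitting, null map simulation, per-map 95th-percentile null statistics |
| `replimap.measurables` | the five base variables, pair-level expansion, orthogonalized OLS, effect sizes, ΔR², MAP aggregation |
| `replimap.pipeline` / `replimap.cli` | experiment orchestration, YAML config, tidy CSV outputs, CLI |

## CLI

```sh
replimap simulate  --config examples/config.yaml --out data/        # write synthetic data
replimap reference --config examples/config.yaml                    # full-sample proportions
replimap run       --config examples/config.yaml --out results/run  # full experiment
replimap measurables --rows results/run/measurables_rows.csv        # regression + MAP
replimap summarize --records results/run/records.csv --out curves.csv
```

`run` writes `records.csv` (one row per task/sort/k/metric/threshold),
`null_curves.csv`, `measurables_rows.csv`, `reference_proportions.json` and
`failures.json` into the output directory; everything is reproducible from
the config seed.

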