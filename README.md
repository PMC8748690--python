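# spherotil

Quantification toolkit for tumor-spheroid / T-cell imaging studies: 3D
spheroid segmentation with infiltrating-lymphocyte densities and dead-volume
kinetics, microscope-based cytotoxicity killing rates, CTL–target cell-couple
morphodynamics classification, caliper tumor-growth statistics (including
exact 2×2 inference), and Boolean-gated marker-combination PCA. Every stage
is exercisable end-to-end on synthetic data with known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `spherotil.io_config` | run configuration, channel-major TIFF stacks, CSV tables, seeding/logging |
| `spherotil.synthetic` | ground-truth generators for every input modality (scenes, area curves, couple tracks, growth cohorts, marker matrices) |
| `spherotil.spheroid_seg` | z-mirror completion → Otsu binarisation → 26-connected labeling → alpha-shape gap filling → anisotropic distance watershed → per-spheroid volume, T-cell count/density, dead volume |
| `spherotil.cytotox` | steepest-window OLS slope of red-object area series, control-normalized killing rate |
| `spherotil.morphodyn` | tight-coupling frame, uropod/off-interface-lamella/translocation classifiers, Kaplan–Meier + log-rank, Fura-2 ratios |
| `spherotil.growth_stats` | modified elliptical volume, R-value growth rate, responder/relapse/remission flags, Fisher exact, Boschloo exact unconditional test, two-proportion z-test, power-based group sizing, outlier exclusion |
| `spherotil.flow_pca` | Boolean AND-combination percentages, arcsine-sqrt/log10 transforms, correlation-scale PCA with cos2/contributions, 95% group ellipses |

## CLI

Every subcommand logs its seed and fully resolved configuration.

```sh
spherotil spheroids --in stacks_dir/ --out records.csv [--config c.yaml]
spherotil cytotox   --in areas.csv   --out rates.csv
spherotil morpho    --in tracks.json --out events.csv
spherotil growth    --in caliper.csv --out stats.csv [--exclude-outliers]
spherotil test2x2   --table 8 2 3 9 --method fisher|boschloo
spherotil pca       --in cells.csv   --out prefix
```

Input formats: multi-page TIFF (one page per z-slice per channel,
channel-major; channel identity by explicit name→index map), CSV tables with
header rows, JSON track files (per-frame vertex lists). Config files are
YAML/JSON mirroring `spherotil.io_config.Config`.

## Synthetic ground truth

`spherotil.synthetic` renders anisotropic half-stacks (3 µm z-steps, cropped
at the spheroid's widest plane), logistic-decline killing curves, parametric
cell-couple outline tracks with injected uropod/lamella/translocation events
at configurable margins, triphasic caliper growth cohorts, and latent-score
marker matrices. All generators are bit-reproducible for a given seed and
return truth objects sufficient to verify every downstream quantity.
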