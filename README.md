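# cardiostain

A tested, reproducible pipeline for quantifying chromogenic (blue-on-pink)
histological staining in serial heart sections and reconstructing the
stained regions in 3D:

- **phantom** — synthetic serial-section generator: heart-like two-lobed
  tissue silhouettes with blue stain patches concentrated on one side of a
  recorded apex-to-base separation line, plus exact ground truth (stain
  masks, per-slice rigid misalignments, per-side pixel counts).
- **segmentation** — conversion to CIE L\*a\*b\* (sRGB/D65), k-means
  clustering of pixel colors (squared Euclidean distance, K initialized
  at 6), and extraction of the stain cluster: the cluster whose centroid is
  nearest a configurable stain reference color, guarded by a
  blue-chromaticity test (centroid b\* < 0). A deterministic K tuner
  (`tune_k`) replaces interactive cluster-count adjustment.
- **quantification** — standardization of each section image to a fixed
  690×970 analysis frame (669 300 pixels), left/right splitting of
  stain-positive pixels by a y-monotone partition polyline (on-line pixels
  go right), per-heart mean ± SEM and percentage aggregation, and a
  two-sample Student's t-test of the two sides (pooled, Welch, and paired
  variants).
- **reconstruction** — pairwise rigid registration of binary stain masks
  (Dice-maximizing exhaustive grid search via FFT cross-correlation with
  sub-pixel/sub-degree refinement), composition into the first slice's
  frame, z-replication (default 7 layers per section) into a 3D binary
  volume, MetaImage (.mhd/.raw) export, and maximum-intensity orthogonal
  projections.
- **pipeline/CLI** — configured, logged, deterministic end-to-end runs.

## CLI

```bash
# full study replica on synthetic data (3 hearts × 5 sections)
cardiostain run-all --outdir out/ --seed 1 --left-fraction 0.89

# individual stages
cardiostain simulate   --outdir sim/ --seed 1
cardiostain segment    --indir sim/ --outdir seg/ --k 6
cardiostain quantify   --maskdir seg/ --annotations lines.json --outdir quant/
cardiostain reconstruct --maskdir seg/ --outdir recon/ --replication-factor 7
```

All subcommands accept `--config config.yaml` (see `RunConfig` for the
schema); per-stage flags override config values. Exit codes: 0 success,
2 configuration error, 3 stage failure. Reruns with the same config and
seed produce byte-identical CSV/JSON outputs.

## Notes

- The `.mhd`/`.raw` volumes are standard MetaImage and load in common
  medical-image viewers (e.g. ITK-SNAP).
- Phantom truth masks use nearest-neighbor resampling under rigid
  perturbation so binary masks stay binary.
- Percentages are computed per slice and then averaged (mean of ratios);
  the pooled ratio of means is available from the per-slice CSVs.
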