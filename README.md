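# neuroqc

No-reference quality-control metrics and automated good/bad flagging for
structural, functional and diffusion MRI (and CT) volumes, with a synthetic
phantom generator so every metric is testable without study data.

## What it computes

**Structural / CT** (`qc smri`): mean slice intensity (MSI), SNR, SVNR, CNR,
CVNR, TCTV, per-axis smoothness (FWHM by the variance-of-derivatives method,
plus resolvable elements) and centre of mass; the `phantom` profile adds the
odd/even slice intensity difference.  The `ct` profile skips tissue
segmentation, so contrast metrics are flagged unavailable rather than
invented.

**Functional** (`qc fmri`): rigid realignment (symmetric Gauss-Newton
registration), framewise displacement (Power convention, 50 mm head radius)
with the FD > 0.5 mm count, DVARS on a median-1000 intensity scale with the
DVARS > 50 count, temporal SNR, SFNR (2nd-order polynomial detrend), outlier
voxel fractions, velocity, signal spectrum statistics, and per-frame
MSI/CoM/FWHM plus per-slice variation.

**Diffusion** (`qc dti`): gradient-table validation (FSL bval/bvec dialect),
per-gradient MSI/SNR/CoM displacement, within-head-mask intensity histograms,
a per-slice descriptive report, and B0/FA/MD/ADC maps from an unweighted
log-linear tensor fit.

**Auto-QC** (`qc calibrate` / `qc decide` / `qc summarize`): z-scoring against
a reference population, closed-interval cutoff flagging, the ≥3-bad-metrics
scan verdict, ROC cutoff calibration (z sweep −5..5 in 0.05 steps, stratified
threefold cross-validation, (sensitivity+specificity)/2 objective),
area-normalised histogram densities with Dice overlap, Pearson correlation
matrices and grouped study summaries.

**Phantoms** (`qc simulate`): nested-ellipsoid structural phantoms with
Gaussian/Rician noise, bias fields, N/2 ghosting and k-space-truncation
ringing; functional series with rigid motion events, polynomial drift and
intensity spikes (frames are rendered analytically at each pose, so motion
ground truth is exact); diffusion series from per-compartment tensors; and a
reference-population generator for calibration experiments.

## CLI examples

```sh
qc simulate smri --seed 42 --out phantom.nii.gz
qc smri phantom.nii.gz --profile t1 --out report.json

qc simulate fmri --spec fmri_spec.yaml --seed 1 --out func.nii.gz
qc fmri func.nii.gz --tr 2.0 --fd-thresh 0.5 --dvars-thresh 50 --out report.json

qc simulate dti --seed 1 --out dwi.nii.gz          # writes dwi.bval / dwi.bvec
qc dti dwi.nii.gz --bval dwi.bval --bvec dwi.bvec --maps-dir maps/ --out report.json

qc calibrate metrics.csv labels.csv --out cutoffs.json --seed 0
qc decide report.json --cutoffs cutoffs.json --threshold 3
qc summarize table.csv --group-by site --out summary.csv
```

Phantom specs are YAML files mirroring the `PhantomSpec` fields, e.g.

```yaml
n_frames: 100
noise_sigma: 2.0
drift_coefficients: [0.0, 3.0, -2.0]
motion_events:
  - {frame: 40, translation_mm: [1.0, 0.0, 0.0], rotation_deg: [0.0, 0.0, 2.0]}
spike_events:
  - {frame: 60, voxel_fraction: 0.05, amplitude_mads: 10.0}
```

All commands are pure functions of (inputs, config, seed): reports contain no
timestamps and fixed-seed reruns are byte-identical.

## Conventions worth knowing

- Voxel indices are 0-based; physical coordinates are `index * voxel_size`
  mm; the slice axis defaults to the third stored axis.
- Standard deviations use the population convention (divisor N).
- The background/head split takes the lowest 10% intensity quantile as
  background; brain extraction is Otsu-within-head + largest 26-connected
  component + closing and hole fill, with an `--brain-mask` bypass.
- Tissue classes come from 3-class 1-D k-means ordered CSF < GM < WM for
  T1-like contrast (reversed for `t2`/`flair` profiles).
- CoM is reported both as absolute centroid and as offset from the grid
  centre; auto-QC consumes the offset magnitude.
- DVARS thresholds apply on the median-1000 intensity scale (50 ≙ 5% signal
  change); pass `normalize=None` in the API for raw units.
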