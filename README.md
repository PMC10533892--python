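# mitopulse

Analysis pipeline for all-optical generation and detection of reactive
oxygen species (ROS) in single mitochondria: a genetically encoded
photosensitizer produces superoxide at a fixed stimulation point in
two-channel time-lapse movies while a ratiometric H2O2 biosensor reports the
response. The package covers the full quantitative chain —

- **`mitopulse.simulate`** — synthetic two-channel movie/trace generator with
  machine-readable ground truth (capsule-shaped mitochondria, Brownian drift,
  distance-attenuated stimulus responses, plateau-then-exponential decay,
  photosensitizer photobleaching, transient elongation, Poisson + Gaussian
  camera noise) plus dose–response sample generation. Replaces undeposited
  raw microscopy data so every downstream stage is testable offline.
- **`mitopulse.segment`** — rolling-ball (morphological opening) background
  subtraction, Gaussian smoothing, threshold segmentation with sub-pixel area
  estimation, per-region measurements in physical units, and greedy
  mutual-nearest-centroid tracking with gap closing.
- **`mitopulse.traces`** — area normalization (counts/µm²), baseline
  normalization (F/F0, dF/F), ratiometric (R/R0) and quench-ratio traces,
  Euclidean distance to the stimulation point, form factor
  (perimeter²/4π·area), spot/proximal/distal population classification
  relative to the cell's maximum distance (HEK 30/70 % and MEF 20/50 %
  presets, 1.5 µm spot radius), and per-frame population summaries.
- **`mitopulse.kinetics`** — plateau-then-single-phase-decay fits (rate K in
  F/F0·min⁻¹, profiled changepoint search), rise half-times (T½), trapezoidal
  AUC, and the one-sided extra sum-of-squares F test for nested model
  comparison.
- **`mitopulse.calibration`** — per-microdomain 4-parameter logistic standard
  curves (with the R² > 0.99 quality gate), baseline/saturation normalization,
  and inverse interpolation of responses into exogenous-H2O2-equivalent
  concentrations with below-baseline/above-saturation exclusion flags.
- **`mitopulse.pipeline` / `mitopulse.cli`** — configuration, run manifests
  with checksums and row counts, deterministic end-to-end orchestration, and
  self-contained test fixtures.

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which checks the pipeline's
oracle-equivalence, recovery, and calibration properties end to end
(generates a 230-frame standard fixture; a few minutes on one CPU).

## CLI

```bash
mitopulse make-fixture --size tiny --seed 0 --out fx/        # synthetic dataset
mitopulse run-all --fixture fx/ --out run/ --seed 0          # full pipeline
mitopulse simulate --seed 0 --out sim/                       # movie + ground truth
mitopulse segment run/../fx/movie.tif --out regions.csv      # per-frame regions
mitopulse track fx/movie.tif --out tracks.csv                # segment + link
mitopulse quantify fx/movie.tif --out q/                     # normalized traces
mitopulse kinetics q/traces.csv fx/movie.tif --out k/        # decay/T½/AUC fits
mitopulse calibrate fx/dose_response.csv --out curves.json \
    --responses fx/responses.csv --equivalents-out eq.csv    # standard curves
```

`run-all` also accepts `--config config.json` with a serialized
`PipelineConfig`. Movies are multi-page TIFF (frame-major, channel-interleaved,
uint16) with a JSON metadata sidecar; all tabular outputs are tidy CSV and all
reports JSON, byte-identical across reruns with a fixed seed.

## Outputs of a pipeline run

| file | contents |
| --- | --- |
| `tracks.csv` | per-(track, frame) measurements: area, perimeter, axes, centroid, channel sums |
| `traces.csv` | tidy normalized traces: dF/F (biosensor), F/F0 (photosensitizer), distance, population |
| `morphology.csv` | per-frame area and form factor per track |
| `amplitudes.csv` | per-track immediate post-pulse dF/F with population label |
| `population_summary.csv` | per-frame n/mean/SEM/proportion per population (+ display smoothing) |
| `kinetics.csv` | plateau-decay fits, T½ and AUC per population and pulse |
| `ftest.json` | extra sum-of-squares F test comparing pulse-1 vs pulse-2 decay |
| `curves.json` / `equivalents.csv` | fitted standard curves and per-cell H2O2 equivalents |
| `manifest.json` | config echo, seed, input checksums, row counts, warnings |
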