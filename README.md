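# holoplankton

A toolkit for in-line phase-shifting digital holography of plankton-like
amplitude objects:

- **`holoplankton.optics`** — scalar-diffraction core: thin-object
  transmission, Fresnel propagation (single-FFT transfer function,
  exactly power-conserving and invertible), plane-wave reference, and
  interference intensity.
- **`holoplankton.gpsdh`** — two-step generalized phase-shifting
  reconstruction: closed-form recovery of the complex object wave from two
  interferograms plus the object/reference intensities, phase-step
  estimation from the data, and refocusing to the object plane.
- **`holoplankton.scenegen`** — procedural plankton-like silhouettes
  (four families), non-overlapping scene composition with YOLO-format
  bounding-box labels, hologram-set synthesis, and reproducible dataset
  builds with train/test splits.
- **`holoplankton.aunet`** — a compact add-skip encoder–decoder for
  single-frame hologram inversion, implemented directly on NumPy with
  hand-written backprop (MSE loss, Adam, staged learning-rate schedule).
  No deep-learning framework required.
- **`holoplankton.metrics`** — SSIM (global and 11×11 Gaussian-window
  modes), MSE, and log-magnitude Fourier spectra.
- **`holoplankton.detect_eval`** — detection scoring against YOLO ground
  truth: IoU, greedy confidence-ordered matching, PR curves, all-point
  interpolated AP, and mAP@0.5. The detector itself is external and
  pluggable; only label export and scoring live here.

## CLI

```sh
# two-step reconstruction of a recorded frame set (I1/I2/Io/Ir as TIFF or PNG)
holoplankton reconstruct --set frames/ --z 2.1 --delta 1.5708 --out rec/

# build a labeled synthetic dataset (images/, targets/, labels/, manifest.yaml)
holoplankton build-dataset --n 550 --ratio 0.909 --seed 0 --profile desk --out ds/

# train the add-skip network on a built dataset
holoplankton train --manifest ds/ --profile desk --seed 0 --out run/

# per-image SSIM/MSE between two image directories
holoplankton eval --pred run_out/ --ref ds/targets/ --metric ssim

# score YOLO-format predictions ("class conf xc yc w h" lines) against labels
holoplankton detect-eval --pred preds/ --truth ds/labels/ --iou 0.5
```

## Scope notes

The full-scale configuration (512×512 grids, 10,000 holograms, 300
training cycles, tens of GPU-hours) is not reproducible on a desk CPU
and is not attempted; the desk profile keeps the same optical model,
reconstruction algebra, network structure, and staged learning-rate
schedule at a size that trains in minutes. Quantities that depend on
external imagery, trained YOLOv5 weights, or specific hardware (overall
detection accuracy, per-class precisions, batch counts, wall-clock
timings) are out of scope and excluded from the acceptance report.
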