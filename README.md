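# mindreach

A hardware-free toolkit for intention-driven assistive-robot simulation:
a self-adaptive Bayesian-LDA decoder for 4-key P300 speller EEG with
information-transfer-rate-aware threshold selection, and an organized
RGB-D perception stack (plane extraction, two-pass region-growing object
segmentation, localization, rigid frame transforms), exercised end to end
on synthetic data.

## Modules

| module | what it does |
| --- | --- |
| `mindreach.synth` | session timing model, flash scheduling, synthetic oddball EEG generation, text-based recording I/O |
| `mindreach.preprocess` | 0.1–20 Hz causal bandpass, 600 ms epoch extraction, 1-in-6 decimation, channel-major feature vectors, round averaging |
| `mindreach.blda` | Bayesian linear discriminant: Gaussian likelihood/prior, closed-form posterior, predictive mean/variance, evidence-framework estimation of the precisions |
| `mindreach.decoder` | online adaptive loop: score normalization, the θ₀ stopping rule (3–8 rounds), offline simulation, threshold selection, Wolpaw ITR |
| `mindreach.vision` | ray-cast synthetic tabletop scenes, 4-neighbor cross-product normals, region-growing plane extraction with boundary closing, convex-hull candidates, two-pass object growing, centroid localization, camera→board→robot transforms |
| `mindreach.recognizer` | the 8-weight-layer CNN (4 conv + 4 FC, 4-way softmax) implemented in NumPy with Adam, plus a synthetic silhouette-crop dataset and rescale/mirror augmentation |
| `mindreach.pipeline` | decision layer: key→command mapping, delivery state machine, end-to-end drinking-task simulation |

## CLI

Everything is reachable through one umbrella command:

```sh
mindreach synth-eeg --trials 40 --rounds 10 --amplitude 5 --noise-sd 2 --seed 1 --out session
mindreach preprocess --in session --low 0.1 --high 20 --step 6 --out features.tsv
mindreach blda-train --recording session --out model.blda
mindreach decode --recording session --model model.blda --theta0 0.5 --report report.tsv
mindreach select-theta --recording session --model model.blda --grid 0:0.95:0.05
mindreach synth-scene --objects 3 --seed 2 --out scene.cloud.tsv
mindreach segment --cloud scene.cloud.tsv --dist 0.04 --out labels.tsv
mindreach frames --calib calib.json --from camera --to robot --apply 0.1,0.2,0.9
mindreach cnn-train --per-class 20 --scale 32 --epochs 5 --seed 0
mindreach run-e2e --tasks 10 --theta0 0.5 --seed 1 --report tasks.tsv
```

All artifacts are plain text (TSV matrices with event sidecars, JSON
calibration files and model archives), so they diff and round-trip
bit-exactly.

## Conventions

- Pixel coordinates are `(row, col)`, 0-based; organized clouds are H×W×3
  camera-frame points in meters, +z along the optical axis; with the
  default top-down camera the scene vertical is the camera z axis (a
  config item everywhere it matters).
- Key ids are 1-based (keys 1–3 deliver the corresponding object, key 4
  sends it back). Feature matrices are P′×Q with observations as columns
  and the constant-1 bias coordinate in the last row.
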