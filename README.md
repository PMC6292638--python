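# bacfinder

Detection and classification of individual bacteria in large 3D
fluorescence microscopy stacks.

Light-sheet fluorescence microscopy of host-associated microbes — for
example gut bacteria in larval zebrafish — produces z-stacks of hundreds of
multi-megapixel slices (~0.16 um/px laterally, ~1 um slice spacing). The
labeled bacteria of interest are few-micron rods scattered among bright
autofluorescent host material, inhomogeneous illumination and camera noise.
`bacfinder` implements the standard two-stage answer for scientists working
with such data:

1. a cheap, deliberately over-inclusive **detection front-end** — per-slice
   histogram equalization, z-averaging and thresholding to mask the organ
   interior; per-slice difference-of-Gaussians (DoG) blob detection; linking
   of blobs across consecutive slices; extraction of a fixed 8×28×28 voxel
   region of interest (ROI, ≈ 8 × 4.5 × 4.5 um) around each candidate; and
2. a **3D convolutional network** that classifies each ROI as *bacterium*
   or *noise*, trained with flip/transpose data augmentation, alongside two
   classical baselines (a 500-tree random forest and an RBF-kernel SVM with
   C = 1 on 31 handcrafted shape/texture/intensity features).

The network is two stride-2 "same"-padded convolutional layers (16 and 32
kernels of 2×5×5 in z, y, x, each followed by 2×2×2 max pooling and
leaky-ReLU), a 1024-unit fully connected layer with dropout 0.5, and a
2-way softmax — 160,594 parameters, trained with Adam. It is implemented
directly on numpy (im2col + BLAS) and trains thousands of ROIs per minute
on one CPU core; no GPU or deep-learning framework is required.

A bundled synthetic-data generator renders rod-shaped cells, realistic
distractor objects, an autofluorescent organ interior, anisotropic PSF blur
and shot/read noise at the native voxel geometry, with full ground truth —
so the entire pipeline, including the evaluation protocols
(leave-one-dataset-out cross-validation, annotator-agreement matrices,
training-size and augmentation curves, two-species transfer learning), runs
and is tested end to end without any external data. See
[docs/methods.md](docs/methods.md) for the model and its assumptions.

## Worked example

```python
import bacfinder as bf

# a synthetic 64x256x256 stack: 20 bacteria + 30 distractors, ground truth
vol, truth = bf.generate_volume(bf.SyntheticSpec(seed=0))

mask = bf.compute_gut_mask(vol)                    # inclusive organ mask
cands = bf.detect_volume(vol, mask=mask.data)      # DoG + z-linking
rois = [bf.extract_roi(vol, c.center_zyx) for c in cands]
print(f"{len(cands)} candidates from {len(truth.objects)} true objects")

from bacfinder.presets import score_detection
recall, precision = score_detection(cands, truth, vol.voxel_size_um)
print(f"recall {recall:.2f}, precision {precision:.2f}")
```

Output (seed 0):

```
83 candidates from 50 true objects
recall 1.00, precision 0.95
```

All 20 bacteria are detected (recall 1.00); 95% of candidates correspond to
a real rendered object (long rods legitimately produce several candidates) — the remainder are noise-induced detections, which
is exactly what the classification stage is for. Training the classifier on
a synthetic labeled corpus of four "fish" and testing on held-out ROIs:

```python
from bacfinder.presets import hard_preset_rois, desk_net_config

train_ds, test_ds = hard_preset_rois(seed=0)      # 4000 train / 1000 test
cfg = desk_net_config(seed=0)                     # 60 epochs, Adam 3e-4
model = bf.train(bf.build_network(cfg), train_ds, cfg)
pred, prob = bf.predict(model, test_ds)
print(f"held-out accuracy {(pred == test_ds.labels).mean():.3f}")
```

```
held-out accuracy 0.920
```

On the same corpus the random forest reaches 0.851 and the SVM 0.833: the
network outperforms the feature-based baselines, with the margin coming
from raw-voxel structure (e.g. the interior intensity profile of a rod)
that 31 summary features cannot retain.

The same functionality is exposed as a CLI (`bacfinder --help`):
`synth-volume`, `synth-rois`, `segment`, `detect`, `extract`, `featurize`,
`train`, `predict`, `transfer`, `crossval`, `curve`, `augcurve`,
`transfer-exp` and `agree` subcommands operate on TIFF stacks, HDF5 ROI
archives and CSV tables.

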