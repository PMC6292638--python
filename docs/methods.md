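# Methods

## Problem setting

`bacfinder` addresses a recurring problem in 3D live fluorescence
microscopy of host-associated bacteria: large anisotropic z-stacks (slices
of a few megapixels at ~0.16 um/px laterally, ~1 um axially) contain
discrete labeled bacteria alongside strong, variable autofluorescence from
host tissue. The pipeline finds bright candidate objects and classifies
each candidate as a bacterium or non-bacterial noise. Detection is cheap
and deliberately over-inclusive; all discriminative power sits in the
classifier operating on small fixed-size crops.

## Pipeline

1. **Organ masking** (`segmentation`). Each slice is histogram-equalized
   using the exact normalized empirical CDF (so the result depends only on
   intensity ranks; the output is then quantized to `n_bins = 256` levels,
   a monotone map that preserves this property). A moving average over
   `window = 30` consecutive slices follows, then a hard threshold
   (default 0.5 of the equalized range), retention of the largest
   26-connected component, and one voxel of dilation. The mask is meant to
   *overestimate* the organ: it only gates where detection runs, so the
   threshold errs toward inclusion. The order equalize → average →
   threshold is fixed.

2. **Blob detection** (`blobs`). Per slice, a scale-normalized
   difference-of-Gaussians stack over the geometric sigma ladder
   {1.0, 1.6, 2.56, 4.096} px (ratio 1.6, bracketing a 0.7 um ≈ 4.3 px
   cell diameter). Detections are strict local maxima over the 3×3×(scale
   ± 1) neighborhood above a response threshold; overlapping detections
   (center distance < √2·σ of the larger) are pruned keeping the higher
   response. The default threshold is 4.5× the robust noise scale
   (1.4826·MAD) of the finest response image: at shot-noise-limited
   backgrounds a 3σ cut admits thousands of spurious local maxima per
   megavoxel, overwhelming downstream stages. Blobs in consecutive slices
   are linked by mutual-nearest-neighbor matching within 5 px; chains
   shorter than 2 slices are dropped, because the axial PSF (σ ≈ 1.2 um)
   guarantees that a real object appears in at least two 1-um slices while
   most noise maxima do not. The 5 px link radius accommodates in-plane
   rods, whose per-slice DoG peaks wander along the ridge between slices.
   Each chain yields one candidate at its maximum-response member — for a
   long rod this centers the ROI on the brightest section, not the
   geometric centroid.

3. **ROI extraction** (`blobs.extract_roi`). A 8×28×28 voxel crop
   (≈ 8 × 4.5 × 4.5 um in z, y, x) around each candidate, zero-padded at
   volume borders, center voxel at index (4, 14, 14).

4. **Classification** (`classify`). The primary classifier is a small 3D
   convolutional network: conv(16 kernels, 2×5×5 in z,y,x, stride 2,
   'same' padding) → leaky-ReLU → 2×2×2 ceil-mode max pool → conv(32
   kernels, same shape) → leaky-ReLU → pool → dense 1024 → leaky-ReLU →
   dropout 0.5 → dense 2 → softmax. The spatial trace is
   (8,28,28)→(4,14,14)→(2,7,7)→(1,4,4)→(1,2,2), flattening to 128
   features and 160,594 trainable parameters. It is implemented directly
   on numpy (im2col + BLAS GEMM in float32, Adam, seeded He
   initialization); a single CPU core sustains roughly two seconds per
   epoch on 4,000 ROIs, so every bundled experiment runs on a laptop-class
   machine. ROIs are min-max normalized to [0, 1] per ROI before entering
   the network. Two feature-based baselines accompany it: a 500-tree
   random forest on the raw 31 features and an RBF-kernel SVM (C = 1) on
   standardized features (standardization fit on the training split only).

## Data augmentation

During every training epoch each ROI independently receives a reflection
along z, y and x (each with probability 0.5) followed by a lateral (y/x)
transpose with probability 0.5. Composition of these generators reaches
exactly 16 distinct transforms. All are physically legal: bacteria have no
preferred orientation, the lateral voxels are isotropic, and the transpose
is restricted to the two lateral axes because z has different physical
scale and extent. The "reflection in x, y and z" is read as three
independent per-axis flips rather than one joint point reflection; the
distinction is invisible in distribution over the group but flagged here
for users comparing implementations.

## The 31 handcrafted features

The baselines use a fixed 31-dimensional representation; the families are
intensity statistics (7), suprathreshold morphology at half-max (4),
second-moment ellipsoid geometry (6), a central-slab ellipse fit (4),
texture (5: gradient statistics, Laplacian energy, co-occurrence contrast
and homogeneity on the central slab quantized to 16 gray levels), and an
azimuthally averaged radial intensity profile at r ∈ {0..4} px (5).
Half-max means `median + 0.5·(max − median)`, robust to background offset.
Features are computed on raw (not background-subtracted) voxels.

Every feature is *exactly* invariant under the 16-transform group: the ROI
is first canonicalized to the lexicographically smallest of its 16
transforms, so all members of an orbit map to bit-identical vectors.
(Direct per-feature invariance would hold only up to floating-point
summation order.) The central slab is the mean of the two middle z-slices,
which is symmetric under the z-flip on the even-depth ROI. An all-zero or
constant ROI produces an all-finite vector with morphology features 0 by
convention.

## Synthetic data model

The generator (`synthgen`) emulates the imaging regime so that every stage
is testable without external data:

* **Bacteria**: capsules (cylinder + hemispherical caps) of uniform
  interior intensity; length uniform in 2-5 um, diameter 0.7 um, uniform
  random 3D orientation, amplitude uniform in 80-220 intensity units.
  Rendering integrates sub-voxel coverage on a (4, 2, 2) per-voxel
  sub-grid so thin rods survive the coarse 1-um axial sampling.
* **Distractors**: sums of 1-4 anisotropic Gaussian lobes in three morphs —
  diffuse multi-lobe clumps (wider and per-voxel dimmer than cells, like
  autofluorescent host cells and mucus), rod-like single lobes whose
  elongation and brightness overlap real cells (these defeat
  feature summaries but differ from capsules in raw intensity profile),
  and compact dim specks.
* **Organ**: a smooth-edged ellipsoid (axes ~0.4 of each volume dimension,
  2 um edge) of elevated background (+60 units over the 100-unit base with
  a 30-unit linear gradient). Objects are placed inside it, at least one
  object length from volume borders, with non-overlap enforced by bounded
  rejection sampling.
* **Optics and noise**: the object field is convolved with an anisotropic
  Gaussian PSF (σ 0.26 um lateral, 1.2 um axial); the background is left
  unblurred because it is smooth by construction (it models diffuse
  autofluorescence already at optical resolution). Shot noise uses the
  Gaussian approximation above 20 expected photons and exact Poisson
  below (`photon_scale` = 3 photons per intensity unit by default);
  additive Gaussian read noise (σ = 3) follows; the result is clipped at
  zero.

Per-"fish" variability: ROI corpora cycle their ROIs through `n_datasets`
synthetic fish, each with its own background level, gradient, read noise
and amplitude scaling drawn from a fish-level generator, emulating
inter-acquisition variability for leave-one-dataset-out protocols. The
default class mix is 38% bacteria / 62% noise. A second "species" preset
(shorter 1.5-3.5 um cells, dimmer and narrower amplitude statistics)
supports the transfer-learning experiment; it is deliberately similar but
not an exact morphological mimic of the default species.

The default difficulty was calibrated once so that the classification task
is neither trivial nor impossible: with the settings above, the feature
baselines reach high-80s accuracy and the ConvNet mid-90s on the hard
preset. What the synthetic corpus does **not** model: bacterial
aggregates, textured/granular autofluorescence, motion, scattering
artifacts, shadowing stripes, or a physically rigorous light-sheet PSF.
Passing tests therefore demonstrate correct mechanics and the *relative*
behavior of the methods, not absolute accuracy on any real dataset.

## Training schedules

`NetConfig` defaults follow the full-scale recipe: Adam at learning rate
1e-4, 120 epochs, batch 64, dropout 0.5, leaky-ReLU slope 0.2 (the slope
and batch size are not dictated by the architecture; 0.2 and 64 are
common-practice values). The bundled experiments run scaled-down corpora
(thousands rather than ~20k ROIs) for CPU-friendly turnaround and use a
"desk" schedule of 60 epochs at learning rate 3e-4: the full-scale recipe
performs ~32k optimizer steps, the scaled corpora only ~4k, and the larger
step size restores a comparable effective training duration (at 1e-4/60
epochs the network is still visibly underconverged). Seeds control weight
initialization, shuffling, augmentation and dropout; training is
deterministic given a seed on a fixed BLAS.

Experiment problem sizes (chosen once for desk-scale turnaround): the
classifier comparison trains on 4 fish × 1,000 ROIs (≈4,000) and tests on
4 × 250 over five seeds; the learning curve uses a 2,000-ROI pool in steps
of 250 with a 25% held-out test set (random-forest classifier, whose
training-size behavior is fast to measure); the augmentation curve starts
from 300 ROIs of a 2,600-ROI corpus and adds 300 fresh images or 300
augmented copies per iteration for two iterations (ConvNet, 30 epochs at
learning rate 1e-4; per-epoch augmentation is disabled in both arms and
all runs within one curve share a single classifier seed, so the arms form
a paired comparison differing only in training-set content — at these
sizes unpaired initialization variance would swamp the few-point effect
being measured); the transfer experiment trains the source network on
2,000 source-species ROIs and compares source-only / cold-start /
warm-start on a 1,200-ROI target corpus with an 80/20 split over five
seeds (40 epochs). The warm-versus-cold difference at this scale is a few
points with seed-to-seed scatter of comparable size, so it is assessed as
a multi-seed majority, not a per-run guarantee.

## Numerical and convention choices

* Index order (z, y, x), 0-based, everywhere; TIFF pages map to z.
* 'Same' padding computes `out = ceil(in / stride)` with the extra padding
  placed at the end; pooling is ceil-mode (odd extents padded with −inf).
  These conventions are required for the stride-2 architecture to be
  well-formed on a depth-8 input (7 → 4, 1 → 1).
* Max-pool backward routes the gradient to the first maximum in each
  block; Adam uses β = (0.9, 0.999), ε = 1e-8 with bias correction.
* The SVM exposes probabilities through a logistic map of its decision
  margin rather than cross-validated calibration, keeping SVM training
  and prediction fully deterministic for fixed data (repeated fits are
  bit-identical; the random forest retains small seed-dependent variance).
* The rolling z-average window is clipped at stack ends (the mean runs
  over the available slices), making constant volumes exact fixed points.
* Detection scoring against ground truth is capsule-aware: a bacterium is
  recalled if a candidate lies within 1 um of its axis segment; a
  candidate is a true positive if it matches any rendered object. This
  avoids penalizing correct detections of long rods whose
  maximum-response section is far from the rod center.
* An empty organ mask is returned flagged (with a warning), never
  silently.

## Known limitations

* The ConvNet runs on a single CPU core; there is no GPU path. At the
  bundled sizes this is minutes per experiment, but full-scale corpora
  (tens of thousands of ROIs, hundreds of epochs) would be slow.
* The exact 31-feature list of historical feature-based pipelines varies
  between implementations; this package fixes its own fully specified 31
  and does not perform feature selection.
* Sub-voxel localization, volumetric (3D) DoG, and aggregate segmentation
  are out of scope; candidates are voxel-resolution and single-cell.
* Synthetic realism is deliberately minimal (see above); conclusions about
  real data require real labeled data, which the I/O layer can ingest
  (TIFF stacks, HDF5 ROI archives, CSV label tables).
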