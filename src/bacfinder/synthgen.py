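"""Synthetic light-sheet volumes and ROI corpora with ground truth.

The generator emulates the imaging regime of single-bacterium light-sheet
fluorescence microscopy in the larval zebrafish gut: bright rod-shaped
(capsule) cells a few microns long, diffuse irregular autofluorescent
distractor objects, a smooth inhomogeneous background, anisotropic
point-spread blur (tighter laterally than axially), shot noise and additive
read noise.  Every entry point is deterministic given its seed, and every
generated object carries ground truth, so the full detection/classification
pipeline is testable without any external data.

Two object classes are rendered:

* **bacteria** — capsules (cylinders with hemispherical caps) of uniform
  interior intensity, random 3D orientation, length drawn from a species
  preset (default 2-5 um, diameter 0.7 um);
* **distractors** — sums of 1-4 anisotropic Gaussian lobes drawn from a
  mixture of morphs: *diffuse* multi-lobe clumps (laterally wider and
  per-voxel dimmer than bacteria, like autofluorescent host cells and mucus),
  *rod-like* single elongated lobes whose summary statistics (elongation,
  brightness) overlap those of real cells, and compact dim *specks*.

Objects are placed inside an "organ": a smooth-edged ellipsoidal region of
elevated background emulating the autofluorescent organ interior, which is
what the inclusive organ mask of :mod:`bacfinder.segmentation` is meant to
find.  The point-spread function is applied to the object field only; the
background model (constant plus a smooth linear gradient plus the organ
plateau) represents diffuse autofluorescence that is already band-limited
at the optical resolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import (
    DEFAULT_VOXEL_SIZE_UM,
    LABEL_BACTERIUM,
    LABEL_NOISE,
    ROI,
    ROI_SHAPE,
    LabeledDataset,
    Volume,
)

CLASS_BACTERIUM = "bacterium"
CLASS_DISTRACTOR = "distractor"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic imaging model.

    Geometric parameters are in microns; intensities are in arbitrary camera
    units.  ``photon_scale`` converts intensity to expected photon counts for
    the shot-noise model (larger = cleaner); ``photon_scale=inf`` disables
    shot noise.  Defaults constitute the "hard" study preset: object and
    distractor intensity distributions overlap enough that classification is
    neither trivial nor impossible.
    """

    volume_shape_zyx: tuple[int, int, int] = (64, 256, 256)
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    n_bacteria: int = 20
    n_distractors: int = 30
    bacterium_length_um: tuple[float, float] = (2.0, 5.0)
    bacterium_diameter_um: float = 0.7
    psf_sigma_um: tuple[float, float] = (0.26, 1.2)  # (lateral, axial)
    amplitude_range: tuple[float, float] = (80.0, 220.0)
    distractor_amplitude_range: tuple[float, float] = (25.0, 110.0)
    background_level: float = 100.0
    background_gradient: float = 30.0
    photon_scale: float = 3.0
    read_noise_sd: float = 3.0
    distractor_morph_weights: tuple[float, float, float] = (0.40, 0.35, 0.25)
    organ_level: float = 60.0
    organ_axes_frac: tuple[float, float, float] = (0.40, 0.40, 0.42)
    organ_edge_sigma_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.volume_shape_zyx) < 1:
            raise ValueError("volume dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.n_bacteria < 0 or self.n_distractors < 0:
            raise ValueError("object counts must be >= 0")
        for rng_pair in (self.bacterium_length_um, self.amplitude_range, self.distractor_amplitude_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"range {rng_pair} must be ordered")
        if self.bacterium_diameter_um <= 0 or min(self.psf_sigma_um) <= 0:
            raise ValueError("geometric parameters must be positive")

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "SyntheticSpec":
        d = dict(d)
        for k in (
            "volume_shape_zyx",
            "voxel_size_um",
            "bacterium_length_um",
            "psf_sigma_um",
            "amplitude_range",
            "distractor_amplitude_range",
            "organ_axes_frac",
            "distractor_morph_weights",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return SyntheticSpec(**d)


def species_b_spec(**overrides) -> SyntheticSpec:
    """A second "species" preset for transfer-learning experiments.

    Shorter cells (1.5-3.5 um) with dimmer amplitude statistics that overlap
    the distractor range, and higher read noise: morphologically similar to
    the default species but not an exact mimic, and hard enough that ~1000
    labeled images leave a from-scratch classifier data-limited (the regime
    transfer learning addresses).
    """
    base = dict(
        bacterium_length_um=(1.5, 3.5),
        amplitude_range=(35.0, 110.0),
        distractor_amplitude_range=(25.0, 120.0),
        background_level=110.0,
        read_noise_sd=4.5,
        seed=1,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@dataclass
class GroundTruthObject:
    cls: str
    center_zyx: tuple[float, float, float]
    orientation: tuple[float, float, float]
    length_um: float
    amplitude: float


@dataclass
class GroundTruth:
    """Ground-truth object list for one synthetic volume."""

    objects: list[GroundTruthObject] = field(default_factory=list)

    def centers(self, cls: str | None = None) -> np.ndarray:
        objs = [o for o in self.objects if cls is None or o.cls == cls]
        if not objs:
            return np.zeros((0, 3))
        return np.array([o.center_zyx for o in objs])

    def to_csv(self, path) -> None:
        rows = [
            {
                "class": o.cls,
                "z": o.center_zyx[0],
                "y": o.center_zyx[1],
                "x": o.center_zyx[2],
                "oz": o.orientation[0],
                "oy": o.orientation[1],
                "ox": o.orientation[2],
                "length_um": o.length_um,
                "amplitude": o.amplitude,
            }
            for o in self.objects
        ]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "GroundTruth":
        df = pd.read_csv(path)
        return GroundTruth(
            [
                GroundTruthObject(
                    r["class"],
                    (r.z, r.y, r.x),
                    (r.oz, r.oy, r.ox),
                    r.length_um,
                    r.amplitude,
                )
                for r in df.itertuples()
            ]
        )


def render_capsule(
    center_zyx: Sequence[float],
    orientation: Sequence[float],
    length_um: float,
    diameter_um: float,
    amplitude: float,
    shape_zyx: Sequence[int],
    voxel_size_um: Sequence[float] = DEFAULT_VOXEL_SIZE_UM,
    out: np.ndarray | None = None,
    supersample: tuple[int, int, int] = (4, 2, 2),
) -> np.ndarray:
    """Render a capsule (rod with hemispherical caps) into a voxel grid.

    Intensity equals ``amplitude`` times the sub-voxel coverage fraction of
    the region within ``diameter_um/2`` (in microns) of the axis segment;
    coverage is estimated on a ``supersample`` sub-grid per voxel so that
    thin rods are sampled correctly on the coarse axial grid.  The field is
    linear in ``amplitude``.  A zero ``length_um`` renders a sphere.
    """
    u = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("orientation must be a nonzero vector")
    u = u / norm
    c = np.asarray(center_zyx, dtype=float)
    vs = np.asarray(voxel_size_um, dtype=float)
    shape = tuple(int(s) for s in shape_zyx)
    radius = diameter_um / 2.0
    half = length_um / 2.0

    if out is None:
        out = np.zeros(shape, dtype=np.float32)

    # bounding box of the capsule in voxel indices, padded by one voxel
    extent_um = half * np.abs(u) + radius
    lo = np.maximum(np.floor(c - extent_um / vs - 1).astype(int), 0)
    hi = np.minimum(np.ceil(c + extent_um / vs + 2).astype(int), shape)
    if np.any(lo >= hi):
        return out

    ss = np.asarray(supersample, dtype=int)
    axes_um = []
    for d in range(3):
        idx = np.arange(lo[d], hi[d], dtype=np.float64)
        offs = (np.arange(ss[d]) + 0.5) / ss[d] - 0.5
        axes_um.append(((idx[:, None] + offs[None, :]) - c[d]) * vs[d])
    zz, yy, xx = axes_um  # (nz, ssz), (ny, ssy), (nx, ssx)

    # point-to-segment distance on the supersampled grid, vectorized
    pz = zz[:, None, None, :, None, None]
    py = yy[None, :, None, None, :, None]
    px = xx[None, None, :, None, None, :]
    t = pz * u[0] + py * u[1] + px * u[2]
    t = np.clip(t, -half, half)
    d2 = (pz - t * u[0]) ** 2 + (py - t * u[1]) ** 2 + (px - t * u[2]) ** 2
    coverage = (d2 <= radius * radius).mean(axis=(3, 4, 5))
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (amplitude * coverage).astype(
        np.float32
    )
    return out


def _render_gaussian_lobe(center_zyx, sigmas_um, amplitude, shape, vs, out):
    """Add one anisotropic Gaussian lobe (evaluated out to 3.5 sigma)."""
    c = np.asarray(center_zyx, dtype=float)
    s_vox = np.asarray(sigmas_um) / np.asarray(vs)
    lo = np.maximum(np.floor(c - 3.5 * s_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c + 3.5 * s_vox + 1).astype(int), shape)
    if np.any(lo >= hi):
        return
    ax = [
        ((np.arange(lo[d], hi[d]) - c[d]) / s_vox[d]) ** 2 for d in range(3)
    ]
    g = np.exp(
        -0.5
        * (
            ax[0][:, None, None]
            + ax[1][None, :, None]
            + ax[2][None, None, :]
        )
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (amplitude * g).astype(np.float32)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: np.ndarray,
    vs: np.ndarray,
    margins_vox: np.ndarray,
    min_sep_um: np.ndarray,
    existing_um: list[np.ndarray],
    accept=None,
    max_tries: int = 200,
) -> list[np.ndarray]:
    """Uniform random centers respecting border margins, pairwise separation
    and an optional acceptance predicate (e.g. inside the organ)."""
    placed: list[np.ndarray] = []
    for i in range(n):
        lo = margins_vox[i]
        hi = shape - 1 - margins_vox[i]
        if np.any(lo > hi):
            raise ValueError("volume too small for requested object margins")
        ok = False
        for _ in range(max_tries):
            c = rng.uniform(lo, hi)
            if accept is not None and not accept(c):
                continue
            c_um = c * vs
            sep = min_sep_um[i]
            if all(
                np.linalg.norm(c_um - p) >= sep for p in existing_um
            ):
                placed.append(c)
                existing_um.append(c_um)
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place object {i + 1}/{n} without overlap after {max_tries} tries"
            )
    return placed


def generate_volume(
    spec: SyntheticSpec, margin_scale: float = 1.0
) -> tuple[Volume, GroundTruth]:
    """Generate one synthetic volume and its ground truth.

    Pipeline: place capsules (uniform positions at least ``margin_scale``
    object lengths from the borders, uniform random 3D orientations) and
    distractors on a background of constant level plus a smooth linear
    gradient; convolve the object field with the anisotropic Gaussian PSF;
    add shot noise (Gaussian approximation above 20 expected photons, exact
    Poisson below) and Gaussian read noise; clip at zero.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.volume_shape_zyx)
    vs = np.asarray(spec.voxel_size_um)
    truth = GroundTruth()
    objects = np.zeros(tuple(shape), dtype=np.float32)

    # organ interior: objects are confined to the elevated-background region
    organ_center = (shape - 1) / 2.0
    organ_semi = np.maximum(np.asarray(spec.organ_axes_frac) * shape, 1.0)

    def inside_organ(c: np.ndarray, frac: float = 0.8) -> bool:
        r2 = float(np.sum(((c - organ_center) / organ_semi) ** 2))
        return r2 <= frac * frac

    accept = inside_organ if spec.organ_level > 0 else None

    # bacteria
    lengths = rng.uniform(*spec.bacterium_length_um, size=spec.n_bacteria)
    existing_um: list[np.ndarray] = []
    margins = np.stack(
        [np.maximum(margin_scale * lengths[i] / vs, 2.0) for i in range(spec.n_bacteria)]
    ) if spec.n_bacteria else np.zeros((0, 3))
    min_sep = lengths + 2 * spec.bacterium_diameter_um if spec.n_bacteria else np.zeros(0)
    centers = _place_centers(
        rng, spec.n_bacteria, shape, vs, margins, min_sep, existing_um, accept
    )
    for i, c in enumerate(centers):
        u = _random_unit_vector(rng)
        amp = rng.uniform(*spec.amplitude_range)
        render_capsule(
            c,
            u,
            lengths[i],
            spec.bacterium_diameter_um,
            amp,
            tuple(shape),
            tuple(vs),
            out=objects,
        )
        truth.objects.append(
            GroundTruthObject(
                CLASS_BACTERIUM, tuple(c), tuple(u), float(lengths[i]), float(amp)
            )
        )

    # distractors: 1-4 anisotropic Gaussian lobes each
    if spec.n_distractors:
        d_margin = np.tile(np.maximum(2.0 / vs, 2.0), (spec.n_distractors, 1))
        d_sep = np.full(spec.n_distractors, 3.0)
        d_centers = _place_centers(
            rng, spec.n_distractors, shape, vs, d_margin, d_sep, existing_um, accept
        )
        for c in d_centers:
            amp = rng.uniform(*spec.distractor_amplitude_range)
            u = _random_unit_vector(rng)
            w = np.cumsum(spec.distractor_morph_weights)
            morph = rng.random() * w[-1]
            if morph < w[0]:  # diffuse multi-lobe clump
                n_lobes = rng.integers(2, 5)
                for k in range(n_lobes):
                    off_um = rng.uniform(-1.2, 1.2, size=3) * np.array([1.5, 1.0, 1.0])
                    lobe_c = c + off_um / vs if k else c
                    s_lat = rng.uniform(0.6, 1.8)
                    sig = np.array([rng.uniform(0.9, 2.2), s_lat * rng.uniform(1.0, 2.0), s_lat])
                    if rng.random() < 0.5:
                        sig[[1, 2]] = sig[[2, 1]]
                    _render_gaussian_lobe(lobe_c, sig, amp * rng.uniform(0.4, 1.0), shape, vs, objects)
            elif morph < w[1]:  # rod-like lobe: cell-scale elongation and brightness
                amp = rng.uniform(*spec.amplitude_range) * rng.uniform(0.5, 0.95)
                s_minor = rng.uniform(0.30, 0.55)
                s_major = rng.uniform(0.8, 2.0)
                sig = np.array([rng.uniform(0.8, 1.3), s_major, s_minor])
                if rng.random() < 0.5:
                    sig[[1, 2]] = sig[[2, 1]]
                _render_gaussian_lobe(c, sig, amp, shape, vs, objects)
            else:  # compact speck
                s_lat = rng.uniform(0.25, 0.5)
                sig = np.array([rng.uniform(0.7, 1.1), s_lat, s_lat])
                _render_gaussian_lobe(c, sig, amp * rng.uniform(0.7, 1.3), shape, vs, objects)
            truth.objects.append(
                GroundTruthObject(
                    CLASS_DISTRACTOR, tuple(c), tuple(u), 0.0, float(amp)
                )
            )

    # anisotropic PSF on the object field (background is already smooth)
    sig_vox = np.array(
        [spec.psf_sigma_um[1], spec.psf_sigma_um[0], spec.psf_sigma_um[0]]
    ) / vs
    if objects.any():
        objects = ndimage.gaussian_filter(objects, sig_vox, mode="constant")

    # background: constant plus smooth linear gradient of random direction
    coeffs = rng.normal(size=3)
    coeffs /= max(np.linalg.norm(coeffs), 1e-12)
    ramps = [
        coeffs[d] * (np.arange(shape[d]) / max(shape[d] - 1, 1) - 0.5)
        for d in range(3)
    ]
    background = (
        spec.background_level
        + spec.background_gradient
        * (ramps[0][:, None, None] + ramps[1][None, :, None] + ramps[2][None, None, :])
    ).astype(np.float32)

    if spec.organ_level > 0:
        ax = [
            ((np.arange(shape[d]) - organ_center[d]) / organ_semi[d]) ** 2
            for d in range(3)
        ]
        r2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
        organ = (r2 <= 1.0).astype(np.float32)
        organ = ndimage.gaussian_filter(organ, spec.organ_edge_sigma_um / vs)
        background = background + np.float32(spec.organ_level) * organ

    signal = objects + background

    # shot noise: Poisson for small expected counts, Gaussian approximation above
    if np.isfinite(spec.photon_scale):
        lam = np.clip(signal, 0, None) * spec.photon_scale
        small = lam < 20.0
        noisy = signal + rng.standard_normal(signal.shape).astype(np.float32) * np.sqrt(
            np.where(small, 0.0, lam)
        ).astype(np.float32) / spec.photon_scale
        if small.any():
            noisy[small] = rng.poisson(lam[small]) / spec.photon_scale
        signal = noisy
    if spec.read_noise_sd > 0:
        signal = signal + rng.standard_normal(signal.shape).astype(
            np.float32
        ) * np.float32(spec.read_noise_sd)
    signal = np.clip(signal, 0, None)

    return Volume(signal, tuple(vs), f"synth-{spec.seed}"), truth


# shape of the mini-volumes used to cut classification ROIs
_MINI_SHAPE = (16, 88, 88)


def _crop_roi(data: np.ndarray, center: np.ndarray) -> np.ndarray:
    """(8, 28, 28) crop with the center voxel at index (4, 14, 14)."""
    cz, cy, cx = np.round(center).astype(int)
    out = np.zeros(ROI_SHAPE, dtype=data.dtype)
    zs, ys, xs = cz - 4, cy - 14, cx - 14
    z0, y0, x0 = max(zs, 0), max(ys, 0), max(xs, 0)
    z1 = min(zs + 8, data.shape[0])
    y1 = min(ys + 28, data.shape[1])
    x1 = min(xs + 28, data.shape[2])
    out[z0 - zs : z1 - zs, y0 - ys : y1 - ys, x0 - xs : x1 - xs] = data[
        z0:z1, y0:y1, x0:x1
    ]
    return out


def generate_roi_dataset(
    spec: SyntheticSpec,
    n_per_class: tuple[int, int] = (38, 62),
    n_datasets: int = 1,
    seed: int | None = None,
) -> LabeledDataset:
    """Generate a labeled ROI corpus of (n_noise, n_bacteria) ROIs per dataset.

    ``n_per_class`` is (noise, bacterium) per synthetic "fish"; the default
    38% bacteria / 62% noise mirrors a hand-labeled corpus mix.  Each of the
    ``n_datasets`` fish gets its own background level, noise draws and
    amplitude scaling (drawn from a per-fish generator) to emulate
    inter-dataset variability; ROIs are cut from freshly generated
    mini-volumes at ground-truth object centers.
    """
    if min(n_per_class) < 0 or max(n_per_class) < 1:
        raise ValueError("n_per_class must request at least one ROI")
    if seed is None:
        seed = spec.seed
    master = np.random.default_rng(seed)
    rois: list[ROI] = []
    n_noise, n_bact = int(n_per_class[0]), int(n_per_class[1])
    vs = np.asarray(spec.voxel_size_um)

    for fish in range(n_datasets):
        fish_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        fish_id = f"fish{fish}"
        fish_spec = spec.replace(
            volume_shape_zyx=_MINI_SHAPE,
            background_level=spec.background_level * fish_rng.uniform(0.8, 1.25),
            background_gradient=spec.background_gradient * fish_rng.uniform(0.6, 1.4),
            read_noise_sd=spec.read_noise_sd * fish_rng.uniform(0.8, 1.3),
            amplitude_range=tuple(
                np.asarray(spec.amplitude_range) * fish_rng.uniform(0.85, 1.15)
            ),
        )
        need = {LABEL_BACTERIUM: n_bact, LABEL_NOISE: n_noise}
        got = {LABEL_BACTERIUM: 0, LABEL_NOISE: 0}
        failures = 0
        while got[LABEL_BACTERIUM] < need[LABEL_BACTERIUM] or got[LABEL_NOISE] < need[LABEL_NOISE]:
            mini = fish_spec.replace(
                n_bacteria=2 if got[LABEL_BACTERIUM] < need[LABEL_BACTERIUM] else 0,
                n_distractors=2 if got[LABEL_NOISE] < need[LABEL_NOISE] else 0,
                seed=int(fish_rng.integers(0, 2**31 - 1)),
            )
            try:
                vol, truth = generate_volume(mini, margin_scale=0.5)
            except ValueError:
                failures += 1
                if failures > 50:  # pragma: no cover - pathological spec
                    raise
                continue
            for obj in truth.objects:
                label = LABEL_BACTERIUM if obj.cls == CLASS_BACTERIUM else LABEL_NOISE
                if got[label] >= need[label]:
                    continue
                center = np.asarray(obj.center_zyx)
                rois.append(
                    ROI(
                        _crop_roi(vol.data, center),
                        tuple(np.round(center).astype(int)),
                        label,
                        fish_id,
                    )
                )
                got[label] += 1
    return LabeledDataset(rois)


def generate_sanity_dataset(
    n: int = 200, seed: int = 0, n_datasets: int = 1
) -> LabeledDataset:
    """A trivially separable corpus: bright centered cube vs flat background.

    Used as a floor test — any functioning classifier should reach
    accuracy 1.0 on it.
    """
    rng = np.random.default_rng(seed)
    rois = []
    for i in range(n):
        label = LABEL_BACTERIUM if i % 2 == 0 else LABEL_NOISE
        base = rng.uniform(40, 60)
        vox = rng.normal(base, 2.0, size=ROI_SHAPE).astype(np.float32)
        if label == LABEL_BACTERIUM:
            vox[2:6, 10:18, 10:18] += base * 4
        vox = np.clip(vox, 0, None)
        rois.append(ROI(vox, (4, 14, 14), label, f"fish{i % n_datasets}"))
    return LabeledDataset(rois)
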