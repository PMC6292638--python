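"""Handcrafted 31-dimensional ROI representation for the feature baselines.

The feature families mix intensity statistics, suprathreshold morphology,
second-moment (ellipsoid) geometry, a central-slice ellipse fit, texture
measures and a radial intensity profile.  Every feature is *exactly*
invariant under the 16-element flip/transpose group used for data
augmentation: the ROI is first canonicalized (the lexicographically smallest
of its 16 transforms is selected), so all transforms of an ROI map to the
identical feature vector bit for bit.  Degenerate inputs (e.g. an all-zero
ROI) yield all-finite vectors with morphology features defined as 0.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix, graycoprops

from .volio import ROI, ROI_SHAPE, LabeledDataset

FEATURE_NAMES: tuple[str, ...] = (
    # intensity statistics
    "int_max",
    "int_mean",
    "int_median",
    "int_sd",
    "int_p10",
    "int_p90",
    "int_peak_contrast",
    # suprathreshold morphology at half-max
    "morph_voxel_count",
    "morph_z_extent",
    "morph_lateral_extent",
    "morph_fill_fraction",
    # second-moment ellipsoid of intensity
    "mom_eig1",
    "mom_eig2",
    "mom_eig3",
    "mom_ratio21",
    "mom_ratio31",
    "mom_com_offset",
    # central-slab ellipse fit at half-max
    "ell_major",
    "ell_minor",
    "ell_eccentricity",
    "ell_area",
    # texture
    "tex_grad_mean",
    "tex_grad_sd",
    "tex_laplace_energy",
    "tex_glcm_contrast",
    "tex_glcm_homogeneity",
    # radial intensity profile (central slab)
    "rad_r0",
    "rad_r1",
    "rad_r2",
    "rad_r3",
    "rad_r4",
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 31

_GLCM_LEVELS = 16

# radial bin masks on the 28x28 central slab, distances from the lateral center
_yy, _xx = np.mgrid[0:28, 0:28]
_RADIUS = np.sqrt((_yy - 13.5) ** 2 + (_xx - 13.5) ** 2)
_RADIAL_MASKS = [(_RADIUS >= r) & (_RADIUS < r + 1) for r in range(5)]


def the_sixteen_transforms(voxels: np.ndarray) -> list[np.ndarray]:
    """All 16 distinct flip/transpose images of an (8, 28, 28) array.

    The group is generated by the three axis flips and the lateral (y/x)
    transpose; composing them yields exactly 16 distinct transforms.
    """
    out = []
    for fz in (False, True):
        for fy in (False, True):
            for fx in (False, True):
                a = voxels
                if fz:
                    a = a[::-1]
                if fy:
                    a = a[:, ::-1]
                if fx:
                    a = a[:, :, ::-1]
                out.append(np.ascontiguousarray(a))
                out.append(np.ascontiguousarray(a.swapaxes(1, 2)))
    return out


def canonicalize(voxels: np.ndarray) -> np.ndarray:
    """The lexicographically smallest of an ROI's 16 flip/transpose images.

    All 16 transforms of an ROI share one canonical form, which makes any
    function of the canonical form exactly invariant under the group.
    """
    best = None
    for t in the_sixteen_transforms(voxels):
        flat = t.ravel()
        if best is None:
            best = flat
            continue
        neq = flat != best
        if neq.any():
            i = int(np.argmax(neq))
            if flat[i] < best[i]:
                best = flat
    return best.reshape(voxels.shape)


def _half_max_threshold(v: np.ndarray) -> float:
    med = float(np.median(v))
    return med + 0.5 * (float(v.max()) - med)


def compute_features(roi: ROI | np.ndarray) -> np.ndarray:
    """Compute the 31 features of one ROI (order matches FEATURE_NAMES)."""
    voxels = roi.voxels if isinstance(roi, ROI) else np.asarray(roi)
    if voxels.shape != ROI_SHAPE:
        raise ValueError(f"expected ROI shape {ROI_SHAPE}, got {voxels.shape}")
    v = canonicalize(voxels.astype(np.float64))
    f = np.zeros(N_FEATURES)

    vmax = float(v.max())
    vmed = float(np.median(v))
    f[0] = vmax
    f[1] = v.mean()
    f[2] = vmed
    f[3] = v.std()
    f[4] = np.percentile(v, 10)
    f[5] = np.percentile(v, 90)
    f[6] = vmax - vmed

    thr = _half_max_threshold(v)
    supra = v > thr
    n_supra = int(supra.sum())
    f[7] = n_supra
    if n_supra:
        zi, yi, xi = np.nonzero(supra)
        z_ext = zi.max() - zi.min() + 1
        y_ext = yi.max() - yi.min() + 1
        x_ext = xi.max() - xi.min() + 1
        f[8] = z_ext
        f[9] = max(y_ext, x_ext)
        f[10] = n_supra / (z_ext * y_ext * x_ext)

        # intensity-weighted second moments of the suprathreshold region
        w = v[supra] - thr
        wsum = w.sum()
        if wsum > 0:
            pts = np.stack([zi, yi, xi]).astype(np.float64)
            com = (pts * w).sum(axis=1) / wsum
            d = pts - com[:, None]
            cov = (d * w) @ d.T / wsum
            eigs = np.sort(np.linalg.eigvalsh(cov))[::-1]
            eigs = np.clip(eigs, 0, None)
            f[11:14] = eigs
            if eigs[0] > 0:
                f[14] = eigs[1] / eigs[0]
                f[15] = eigs[2] / eigs[0]
            center = (np.array(ROI_SHAPE) - 1) / 2.0
            f[16] = np.linalg.norm(com - center)

    # central slab: mean of the two middle slices (invariant under z-flip)
    slab = 0.5 * (v[3] + v[4])
    sthr = _half_max_threshold(slab)
    sm = slab > sthr
    n2 = int(sm.sum())
    if n2:
        yi, xi = np.nonzero(sm)
        w = slab[sm] - sthr
        wsum = w.sum()
        if wsum > 0:
            pts = np.stack([yi, xi]).astype(np.float64)
            com = (pts * w).sum(axis=1) / wsum
            d = pts - com[:, None]
            cov = (d * w) @ d.T / wsum
            e = np.sort(np.linalg.eigvalsh(cov))[::-1]
            e = np.clip(e, 0, None)
            major = 4.0 * np.sqrt(e[0])
            minor = 4.0 * np.sqrt(e[1])
            f[17] = major
            f[18] = minor
            if major > 0:
                f[19] = np.sqrt(max(1.0 - (minor / major) ** 2, 0.0))
        f[20] = n2

    gz, gy, gx = np.gradient(v)
    gmag = np.sqrt(gz * gz + gy * gy + gx * gx)
    f[21] = gmag.mean()
    f[22] = gmag.std()
    lap = (
        -6.0 * v
        + np.roll(v, 1, 0)
        + np.roll(v, -1, 0)
        + np.roll(v, 1, 1)
        + np.roll(v, -1, 1)
        + np.roll(v, 1, 2)
        + np.roll(v, -1, 2)
    )
    f[23] = float((lap**2).mean())

    # co-occurrence texture on the quantized central slab
    lo, hi = slab.min(), slab.max()
    if hi > lo:
        q = np.minimum(
            ((slab - lo) / (hi - lo) * _GLCM_LEVELS).astype(np.uint8),
            _GLCM_LEVELS - 1,
        )
        glcm = graycomatrix(
            q,
            distances=[1],
            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=_GLCM_LEVELS,
            symmetric=True,
            normed=True,
        )
        f[24] = graycoprops(glcm, "contrast").mean()
        f[25] = graycoprops(glcm, "homogeneity").mean()

    for r in range(5):
        f[26 + r] = slab[_RADIAL_MASKS[r]].mean()

    if not np.isfinite(f).all():  # pragma: no cover - defensive
        f[~np.isfinite(f)] = 0.0
    return f


def feature_matrix(ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, 31) and label vector, rows in dataset order."""
    X = np.stack([compute_features(r) for r in ds])
    return X, ds.labels


def standardization_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and SD (zero-variance columns get SD 1).

    Fit these on the training split only and apply to both splits.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def apply_standardization(
    X: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    return (X - mean) / sd
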