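"""Rough organ-interior masking to restrict where blob detection runs.

The mask is deliberately inclusive ("overestimates" the organ): it only
gates detection, so false mask area merely costs compute while missed mask
area loses objects.  Pipeline: per-slice histogram equalization, a moving
average along z, hard thresholding, then keep the largest 26-connected
component and dilate it by one voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from .volio import Volume


@dataclass
class MaskVolume:
    """Binary mask matching a source volume's shape."""

    data: np.ndarray
    threshold_used: float
    is_empty: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")


def equalize_slice(slice_2d: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Histogram-equalize one z-slice to (0, 1].

    The output is the exact normalized empirical CDF of the slice applied to
    itself: a monotone (rank-preserving) intensity map that depends only on
    the intensity ranks, which makes downstream thresholds comparable across
    slices with very different illumination.  The result is then quantized
    to ``n_bins`` levels (a monotone map, so rank-dependence is preserved;
    value-range binning as in classic histogram equalization would not be
    exactly invariant under monotone intensity relabelings).
    """
    slice_2d = np.asarray(slice_2d)
    if slice_2d.size == 0:
        raise ValueError("slice must be nonempty")
    _, inv, counts = np.unique(slice_2d, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / slice_2d.size
    out = cdf[inv].reshape(slice_2d.shape)
    if n_bins:
        out = np.ceil(out * n_bins) / n_bins
    return out


def rolling_mean_z(v: Volume, window: int = 30) -> Volume:
    """Moving average over up to ``window`` consecutive slices along z.

    At the ends of the stack the window is clipped to the available slices
    (e.g. values 1..5 with window 3 average to 1.5, 2, 3, 4, 4.5).
    Constant volumes are fixed points; ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    data = v.data.astype(np.float64)
    nz = data.shape[0]
    before = (window - 1) // 2
    after = window // 2
    csum = np.concatenate([np.zeros((1,) + data.shape[1:]), np.cumsum(data, axis=0)])
    lo = np.maximum(np.arange(nz) - before, 0)
    hi = np.minimum(np.arange(nz) + after + 1, nz)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None, None]
    return Volume(out, v.voxel_size_um, v.dataset_id)


def compute_gut_mask(
    v: Volume, threshold: float = 0.5, window: int = 30, n_bins: int = 256
) -> MaskVolume:
    """Compute the inclusive organ mask.

    Equalize each slice, average along z, threshold at ``threshold`` (a
    fraction of the equalized [0, 1] range), keep the largest 26-connected
    component, dilate by one voxel.  An empty thresholded mask is returned
    flagged ``is_empty`` with a warning rather than failing silently.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    eq = np.stack([equalize_slice(s, n_bins) for s in v.data])
    smoothed = rolling_mean_z(Volume(eq, v.voxel_size_um, v.dataset_id), window).data
    mask = smoothed > threshold
    if not mask.any():
        warnings.warn(
            "gut mask is empty after thresholding; detection would see nothing",
            stacklevel=2,
        )
        return MaskVolume(mask, threshold, is_empty=True)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == np.argmax(sizes)
    mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return MaskVolume(mask, threshold)
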