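"""Volume, ROI and label I/O with explicit coordinate conventions.

All 3D grids are indexed ``(z, y, x)``, 0-based: TIFF pages map to z in
ascending order and pixel ``(row, col)`` maps to ``(y, x)``.  Volumes carry a
voxel size in microns; the default geometry is that of a light-sheet scan of
a larval zebrafish gut (0.1625 um/px laterally, 1 um slice spacing).

Classification regions of interest (ROIs) are fixed 8x28x28 voxel crops
(~8 x 4.5 x 4.5 um) around detected candidate objects.  Labels are integers:
0 = noise, 1 = bacterium, -1 = unlabeled.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

#: (z, y, x) voxel edge lengths in microns for the default acquisition geometry.
DEFAULT_VOXEL_SIZE_UM: tuple[float, float, float] = (1.0, 0.1625, 0.1625)

#: (z, y, x) shape of a classification ROI.
ROI_SHAPE: tuple[int, int, int] = (8, 28, 28)

LABEL_NOISE = 0
LABEL_BACTERIUM = 1
LABEL_UNLABELED = -1
_VALID_LABELS = (LABEL_NOISE, LABEL_BACTERIUM, LABEL_UNLABELED)


@dataclass
class Volume:
    """A 3D intensity grid with voxel-size metadata.

    Parameters
    ----------
    data
        3D array indexed (z, y, x).  Intensities must be finite and >= 0.
    voxel_size_um
        (z, y, x) voxel edge lengths in microns.
    dataset_id
        Identifier of the acquisition (one scan of one specimen).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        vs = tuple(float(s) for s in self.voxel_size_um)
        if len(vs) != 3 or any(s <= 0 for s in vs):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_um}")
        self.voxel_size_um = vs
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROI:
    """A 8x28x28 voxel crop centered on a candidate detection."""

    voxels: np.ndarray
    center_zyx: tuple[int, int, int] = (0, 0, 0)
    label: int = LABEL_UNLABELED
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != ROI_SHAPE:
            raise ValueError(f"ROI must have shape {ROI_SHAPE}, got {self.voxels.shape}")
        if self.label not in _VALID_LABELS:
            raise ValueError(f"label must be one of {_VALID_LABELS}, got {self.label}")
        self.center_zyx = tuple(int(c) for c in self.center_zyx)


class LabeledDataset:
    """An ordered collection of labeled ROIs, the unit of cross-validation.

    Every ROI must carry a label in {0, 1} and a nonempty dataset id.
    Iteration order is stable (insertion order).
    """

    def __init__(self, rois: Iterable[ROI]):
        self.rois: list[ROI] = list(rois)
        if not self.rois:
            raise ValueError("a LabeledDataset must contain at least one ROI")
        for r in self.rois:
            if r.label == LABEL_UNLABELED:
                raise ValueError("every ROI in a LabeledDataset must be labeled")
            if not r.dataset_id:
                raise ValueError("every ROI must carry a nonempty dataset_id")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[ROI]:
        return iter(self.rois)

    def __getitem__(self, i: int) -> ROI:
        return self.rois[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.rois], dtype=np.int64)

    @property
    def dataset_ids(self) -> list[str]:
        return [r.dataset_id for r in self.rois]

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def voxel_array(self) -> np.ndarray:
        """All ROI voxels stacked into an (n, 8, 28, 28) array."""
        return np.stack([r.voxels for r in self.rois])

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.rois[int(i)] for i in indices])

    def split_by_dataset(self) -> dict[str, "LabeledDataset"]:
        """Partition into per-acquisition datasets, preserving order."""
        groups: dict[str, list[ROI]] = {}
        for r in self.rois:
            groups.setdefault(r.dataset_id, []).append(r)
        return {k: LabeledDataset(v) for k, v in groups.items()}

    @staticmethod
    def concat(parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        rois: list[ROI] = []
        for p in parts:
            rois.extend(p.rois)
        return LabeledDataset(rois)


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not files:
        raise ValueError(f"no TIFF slices found in directory {path}")
    slices = [tifffile.imread(str(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    if slices[0].ndim != 2:
        raise ValueError(f"slices in {path} are not 2D (shape {slices[0].shape})")
    return np.stack(slices, axis=0)


def read_stack(
    path: str | os.PathLike,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    dataset_id: str | None = None,
) -> Volume:
    """Read a z-stack from a multi-page TIFF or a directory of per-slice TIFFs.

    Pages (or files in filename order) map to z ascending; integer pixel data
    is kept as read, without rescaling.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such stack: {p}")
    if p.is_dir():
        data = _read_slice_dir(p)
    else:
        data = tifffile.imread(str(p))
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got shape {data.shape}")
    if data.shape[0] == 0:
        raise ValueError("stack contains zero slices")
    return Volume(data, voxel_size_um, dataset_id or p.stem)


def write_stack(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF, one z-slice per page."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(p), v.data, photometric="minisblack")


def save_roi_set(ds: LabeledDataset, path: str | os.PathLike) -> None:
    """Save a labeled ROI set as a single HDF5 container.

    Datasets: ``voxels`` (n, 8, 28, 28), ``labels`` (n,), ``dataset_ids``
    (n, utf-8 strings) and ``centers`` (n, 3).  Round-trip is lossless and
    order-preserving.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    voxels = ds.voxel_array()
    with h5py.File(str(p), "w") as f:
        f.create_dataset("voxels", data=voxels, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset(
            "dataset_ids",
            data=np.array(ds.dataset_ids, dtype=h5py.string_dtype("utf-8")),
        )
        f.create_dataset(
            "centers", data=np.array([r.center_zyx for r in ds.rois], dtype=np.int64)
        )


def load_roi_set(path: str | os.PathLike) -> LabeledDataset:
    """Load an HDF5 ROI archive written by :func:`save_roi_set`."""
    with h5py.File(str(path), "r") as f:
        for name in ("voxels", "labels", "dataset_ids", "centers"):
            if name not in f:
                raise ValueError(f"corrupt ROI archive: missing dataset '{name}'")
        voxels = f["voxels"][...]
        labels = f["labels"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["dataset_ids"][...]]
        centers = f["centers"][...]
    n = voxels.shape[0]
    if voxels.shape[1:] != ROI_SHAPE:
        raise ValueError(f"archive ROIs have shape {voxels.shape[1:]}, expected {ROI_SHAPE}")
    if not (labels.shape == (n,) and len(ids) == n and centers.shape == (n, 3)):
        raise ValueError("shape mismatch between ROI archive arrays")
    return LabeledDataset(
        ROI(voxels[i], tuple(centers[i]), int(labels[i]), ids[i]) for i in range(n)
    )


def write_label_csv(ds: LabeledDataset, path: str | os.PathLike, annotator_id: str = "") -> None:
    """Write labels as a CSV table (roi_index, label, annotator_id)."""
    pd.DataFrame(
        {
            "roi_index": np.arange(len(ds)),
            "label": ds.labels,
            "annotator_id": annotator_id,
        }
    ).to_csv(path, index=False)


def read_label_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read an external label table with columns roi_index, label, annotator_id."""
    df = pd.read_csv(path)
    missing = {"roi_index", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns {sorted(missing)}")
    return df


def load_json_config(path: str | os.PathLike) -> dict:
    with open(path) as f:
        return json.load(f)


def save_json_config(cfg: dict, path: str | os.PathLike) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as f:
        json.dump(cfg, f, indent=2, sort_keys=True)
        f.write("\n")
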