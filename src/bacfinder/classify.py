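"""Classifier training: 3D ConvNet with flip/transpose augmentation, plus
random-forest and SVM baselines and warm-started (transfer) training.

The ConvNet (see :mod:`bacfinder._net`) consumes raw ROI voxels normalized
per ROI to [0, 1]; the baselines consume the 31 handcrafted features of
:mod:`bacfinder.features`.  Augmentation follows the scheme used during
training of the original classifier: each epoch every ROI independently
receives a reflection along z, y and x (each with probability 0.5) followed
by a lateral transpose with probability 0.5 — 16 reachable transforms, all
physically legal because the lateral voxels are isotropic and bacteria have
no preferred orientation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from ._net import ConvNet3D
from .features import (
    apply_standardization,
    compute_features,
    feature_matrix,
    standardization_params,
)
from .volio import ROI, LabeledDataset


@dataclass
class NetConfig:
    """Hyperparameters of the 3D ConvNet.

    Defaults: 16 then 32 kernels of shape 2x5x5 (z, y, x) at stride 2 with
    'same' padding, each followed by 2x2x2 ceil-mode max pooling; a
    1024-unit fully connected layer with dropout 0.5; leaky-ReLU (slope
    0.2); Adam at learning rate 1e-4; 120 epochs of minibatch size 64 with
    per-epoch augmentation.
    """

    kernels_layer1: int = 16
    kernels_layer2: int | None = None  # None -> 2 * kernels_layer1
    kernel_zyx: tuple[int, int, int] = (2, 5, 5)
    stride: tuple[int, int, int] = (2, 2, 2)
    pool: tuple[int, int, int] = (2, 2, 2)
    fc_units: int = 1024
    dropout: float = 0.5
    leaky_slope: float = 0.2
    learning_rate: float = 1e-4
    epochs: int = 120
    batch_size: int = 64
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernels_layer1 < 1 or self.fc_units < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid training schedule")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "NetConfig":
        d = dict(d)
        for k in ("kernel_zyx", "stride", "pool"):
            if k in d:
                d[k] = tuple(d[k])
        return NetConfig(**d)


@dataclass
class TrainedModel:
    """A predict-capable model plus config and training provenance."""

    kind: str  # convnet | random_forest | svm
    model: object
    config: object = None
    provenance: dict = field(default_factory=dict)
    loss_log: list[float] = field(default_factory=list)
    # feature standardization (svm); None for raw-feature / voxel models
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None


def build_network(cfg: NetConfig | None = None) -> ConvNet3D:
    """Build the untrained ConvNet for the given config."""
    return ConvNet3D(cfg or NetConfig())


def normalize_rois(voxels: np.ndarray) -> np.ndarray:
    """Per-ROI min-max normalization to [0, 1] (flat ROIs map to zeros)."""
    v = voxels.astype(np.float32)
    flat = v.reshape(v.shape[0], -1)
    lo = flat.min(axis=1)[:, None, None, None]
    hi = flat.max(axis=1)[:, None, None, None]
    scale = np.where(hi > lo, hi - lo, 1.0)
    return (v - lo) / scale


def augment(roi: ROI, rng: np.random.Generator) -> ROI:
    """Randomly flip each axis (p=0.5 each), then transpose y/x (p=0.5)."""
    v = roi.voxels
    if rng.random() < 0.5:
        v = v[::-1]
    if rng.random() < 0.5:
        v = v[:, ::-1]
    if rng.random() < 0.5:
        v = v[:, :, ::-1]
    if rng.random() < 0.5:
        v = v.swapaxes(1, 2)
    return ROI(np.ascontiguousarray(v), roi.center_zyx, roi.label, roi.dataset_id)


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized per-image augmentation of an (N, 8, 28, 28) array."""
    draws = rng.random((x.shape[0], 4))
    out = x.copy()
    for code in range(16):
        fz, fy, fx, tr = (code >> 3) & 1, (code >> 2) & 1, (code >> 1) & 1, code & 1
        sel = (
            ((draws[:, 0] < 0.5) == bool(fz))
            & ((draws[:, 1] < 0.5) == bool(fy))
            & ((draws[:, 2] < 0.5) == bool(fx))
            & ((draws[:, 3] < 0.5) == bool(tr))
        )
        if not sel.any():
            continue
        sub = x[sel]
        if fz:
            sub = sub[:, ::-1]
        if fy:
            sub = sub[:, :, ::-1]
        if fx:
            sub = sub[:, :, :, ::-1]
        if tr:
            sub = sub.swapaxes(2, 3)
        out[sel] = sub
    return out


def train(
    net: ConvNet3D,
    ds: LabeledDataset,
    cfg: NetConfig | None = None,
    warm_start_of: str | None = None,
) -> TrainedModel:
    """Train the ConvNet on a labeled dataset.

    Runs ``cfg.epochs`` passes over shuffled minibatches with fresh
    per-image augmentation each epoch and Adam updates; records the mean
    training loss per epoch.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or net.cfg
    labels = ds.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes to be present")
    x = normalize_rois(ds.voxel_array())
    y = labels.astype(np.int64)
    rng = np.random.default_rng(cfg.seed + 1)
    n = x.shape[0]
    loss_log: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        xe = _augment_batch(x[order], rng) if cfg.augment else x[order]
        ye = y[order]
        losses = []
        for i in range(0, n, cfg.batch_size):
            loss, grads = net.loss_and_grads(xe[i : i + cfg.batch_size], ye[i : i + cfg.batch_size], rng)
            net.adam_step(grads)
            losses.append(loss)
        loss_log.append(float(np.mean(losses)))
    return TrainedModel(
        kind="convnet",
        model=net,
        config=cfg,
        provenance={
            "dataset_ids": sorted(set(ds.dataset_ids)),
            "n_train": n,
            "seed": cfg.seed,
            "epochs_run": cfg.epochs,
            "warm_start": warm_start_of,
        },
        loss_log=loss_log,
    )


def predict(model: TrainedModel, rois) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class probabilities for ROIs.

    ``rois`` may be a LabeledDataset, a sequence of ROI, or a voxel array.
    No augmentation is applied at inference and dropout is disabled, so
    repeated calls give identical output.
    """
    if isinstance(rois, LabeledDataset):
        voxels = rois.voxel_array()
        roi_list = rois.rois
    elif isinstance(rois, np.ndarray):
        voxels = rois
        roi_list = None
    else:
        roi_list = list(rois)
        voxels = np.stack([r.voxels for r in roi_list])

    if model.kind == "convnet":
        probs = model.model.predict_proba(normalize_rois(voxels))
    else:
        X = np.stack([compute_features(v) for v in voxels])
        if model.feature_mean is not None:
            X = apply_standardization(X, model.feature_mean, model.feature_sd)
        probs = model.model.predict_proba(X)
    labels = probs.argmax(axis=1)
    return labels, probs


def train_baseline(
    kind: str,
    features_or_ds,
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train a feature-based baseline: 500-tree random forest or RBF SVM (C=1).

    Accepts either a precomputed (features, labels) pair or a LabeledDataset
    (features are then computed internally).  SVM features are standardized
    with parameters fit on the training data; SVM training is deterministic
    for fixed data.
    """
    if isinstance(features_or_ds, LabeledDataset):
        X, y = feature_matrix(features_or_ds)
    else:
        X = np.asarray(features_or_ds)
        y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes to be present")
    mean = sd = None
    if kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif kind == "svm":
        mean, sd = standardization_params(X)
        X = apply_standardization(X, mean, sd)
        clf = SVC(kernel="rbf", C=1.0)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    clf.fit(X, y)
    model = clf
    if kind == "svm":
        model = _SVCWithProba(clf)
    return TrainedModel(
        kind=kind,
        model=model,
        config={"kind": kind, "seed": seed},
        provenance={"n_train": int(len(y)), "seed": seed},
        feature_mean=mean,
        feature_sd=sd,
    )


class _SVCWithProba:
    """Deterministic probability shim: decision margin through a logistic map.

    ``SVC(probability=True)`` runs internal cross-validated Platt scaling
    with its own randomness; using the decision function directly keeps SVM
    training and prediction fully deterministic for fixed data.
    """

    def __init__(self, svc: SVC):
        self.svc = svc

    def predict_proba(self, X) -> np.ndarray:
        margin = self.svc.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-margin))
        return np.stack([1.0 - p1, p1], axis=1)


def transfer_train(
    source: TrainedModel, target_ds: LabeledDataset, cfg: NetConfig | None = None
) -> TrainedModel:
    """Warm-started training: initialize every layer from ``source`` weights.

    All layers remain trainable (no freezing).  ``cfg.epochs == 0`` returns
    a model predicting identically to the source.
    """
    if source.kind != "convnet":
        raise ValueError("transfer_train requires a convnet source model")
    cfg = cfg or source.config
    net = build_network(cfg)
    net.set_weights(source.model.get_weights())  # raises on topology mismatch
    if cfg.epochs == 0:
        return TrainedModel(
            kind="convnet",
            model=net,
            config=cfg,
            provenance={**source.provenance, "warm_start": "source", "epochs_run": 0},
            loss_log=[],
        )
    return train(net, target_ds, cfg, warm_start_of="source")


# --- model container I/O -------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Persist a convnet model (weights + config + provenance) as .npz."""
    if model.kind != "convnet":
        raise ValueError("only convnet models are persisted in this container")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps(
        {
            "kind": model.kind,
            "config": model.config.to_dict(),
            "provenance": model.provenance,
            "loss_log": model.loss_log,
        }
    )
    np.savez(p, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.model.get_weights())


def load_model(path) -> TrainedModel:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        weights = {k: f[k] for k in f.files if k != "__meta__"}
    cfg = NetConfig.from_dict(meta["config"])
    net = build_network(cfg)
    net.set_weights(weights)
    return TrainedModel(
        kind="convnet",
        model=net,
        config=cfg,
        provenance=meta["provenance"],
        loss_log=meta["loss_log"],
    )
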