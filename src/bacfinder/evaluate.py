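"""Evaluation protocols: accuracy, agreement matrices, leave-one-dataset-out
cross-validation, training-size curves, augmentation-vs-new-data curves, and
the two-species transfer-learning experiment.

Every protocol records a machine-readable result table (pandas DataFrame)
plus the fully resolved configuration, and draws all of its randomness from
a single top-level seed.  Experiment sizes are configurable; the bundled
presets run the same protocol structure as full-scale studies at a few
thousand ROIs so that a complete comparison executes in minutes on one CPU
core.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (
    NetConfig,
    TrainedModel,
    build_network,
    predict,
    train,
    train_baseline,
    transfer_train,
)
from .features import feature_matrix
from .volio import LabeledDataset


def accuracy(truth: Sequence[int], pred: Sequence[int]) -> float:
    """Fraction of positions where two label vectors agree."""
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    return float((t == p).mean())


@dataclass
class AgreementMatrix:
    """Pairwise agreement fractions between annotators (human or machine)."""

    annotator_ids: list[str]
    values: np.ndarray

    def summary(self) -> tuple[float, float]:
        """Mean and SD of the off-diagonal pairwise agreements."""
        n = len(self.annotator_ids)
        off = self.values[~np.eye(n, dtype=bool)]
        return float(off.mean()), float(off.std())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.annotator_ids, columns=self.annotator_ids)


def agreement_matrix(
    labelings: Sequence[Sequence[int]], ids: Sequence[str] | None = None
) -> AgreementMatrix:
    """Pairwise agreement between label vectors (symmetric, unit diagonal).

    Classifier predictions can be appended as an extra "annotator" to compare
    machine-human against human-human consistency.
    """
    mats = [np.asarray(l) for l in labelings]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("all labelings must have the same length")
    n = len(mats)
    ids = list(ids) if ids is not None else [f"annotator{i}" for i in range(n)]
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = accuracy(mats[i], mats[j])
    return AgreementMatrix(ids, vals)


@dataclass
class ClassifierSpec:
    """Which classifier a protocol trains: convnet, random_forest or svm."""

    kind: str = "convnet"
    net: NetConfig | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("convnet", "random_forest", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class ExperimentResult:
    """Result table of one protocol run plus its resolved configuration."""

    protocol: str
    rows: pd.DataFrame
    config: dict = field(default_factory=dict)

    def save(self, out_dir, stem: str | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = stem or self.protocol
        self.rows.to_csv(out / f"{stem}.csv", index=False)
        import json

        with open(out / f"{stem}_config.json", "w") as f:
            json.dump(self.config, f, indent=2, sort_keys=True, default=str)
            f.write("\n")


def _fit(spec: ClassifierSpec, train_ds: LabeledDataset, seed: int,
         X: np.ndarray | None = None, y: np.ndarray | None = None) -> TrainedModel:
    if spec.kind == "convnet":
        cfg = dataclasses.replace(spec.net or NetConfig(), seed=seed)
        return train(build_network(cfg), train_ds, cfg)
    if X is None:
        X, y = feature_matrix(train_ds)
    return train_baseline(spec.kind, X, y, seed=seed)


def _eval(model: TrainedModel, test_ds: LabeledDataset,
          X_test: np.ndarray | None = None) -> float:
    if model.kind == "convnet" or X_test is None:
        pred, _ = predict(model, test_ds)
    else:
        X = X_test
        if model.feature_mean is not None:
            from .features import apply_standardization

            X = apply_standardization(X, model.feature_mean, model.feature_sd)
        pred = model.model.predict_proba(X).argmax(axis=1)
    return accuracy(test_ds.labels, pred)


def _maybe_features(spec: ClassifierSpec, ds: LabeledDataset):
    if spec.kind == "convnet":
        return None, None
    return feature_matrix(ds)


def leave_one_dataset_out(
    datasets: Sequence[LabeledDataset],
    spec: ClassifierSpec,
    reps: int = 3,
    seed: int = 0,
) -> ExperimentResult:
    """Train on all datasets but one, test on the held-out one, cycling.

    Each train/test combination is repeated ``reps`` times with a fresh seed
    to expose training variance.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    master = np.random.default_rng(seed)
    # features computed once per dataset for the baselines
    feats = [
        _maybe_features(spec, ds) for ds in datasets
    ]
    rows = []
    for held in range(len(datasets)):
        train_parts = [d for i, d in enumerate(datasets) if i != held]
        train_ds = LabeledDataset.concat(train_parts)
        if len(np.unique(train_ds.labels)) < 2:
            raise ValueError("training union lacks one of the classes")
        if spec.kind != "convnet":
            X_tr = np.concatenate([feats[i][0] for i in range(len(datasets)) if i != held])
            y_tr = np.concatenate([feats[i][1] for i in range(len(datasets)) if i != held])
        else:
            X_tr = y_tr = None
        held_id = datasets[held][0].dataset_id
        for rep in range(reps):
            rep_seed = int(master.integers(0, 2**31 - 1))
            model = _fit(spec, train_ds, rep_seed, X_tr, y_tr)
            acc = _eval(model, datasets[held], feats[held][0])
            rows.append(
                {
                    "held_out": held_id,
                    "rep": rep,
                    "seed": rep_seed,
                    "classifier": spec.kind,
                    "n_train": len(train_ds),
                    "accuracy": acc,
                }
            )
    return ExperimentResult(
        "leave_one_dataset_out",
        pd.DataFrame(rows),
        {"classifier": spec.kind, "reps": reps, "seed": seed,
         "net": spec.net.to_dict() if spec.net else None},
    )


def _split_indices(n: int, frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_a = int(round(n * frac))
    return idx[:n_a], idx[n_a:]


def learning_curve(
    datasets: Sequence[LabeledDataset],
    mode: str,
    spec: ClassifierSpec,
    step: int = 1500,
    test_frac: float = 0.25,
    seed: int = 0,
) -> ExperimentResult:
    """Accuracy versus training-set size with a fixed held-out test set.

    ``test_frac`` of each dataset is set aside once; the test set never
    changes across iterations.  Mode ``new_datasets`` grows the training set
    by adding whole datasets' remaining images in sequence (more data *and*
    more biological diversity); mode ``train_test_split`` grows it by adding
    ``step`` images drawn from the shuffled pooled remainder (more data,
    same diversity).  The final iteration of both modes uses the identical
    full training pool.
    """
    if mode not in ("new_datasets", "train_test_split"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    test_parts, train_parts = [], []
    for ds in datasets:
        t_idx, r_idx = _split_indices(len(ds), test_frac, rng)
        test_parts.append(ds.subset(sorted(t_idx)))
        train_parts.append(ds.subset(sorted(r_idx)))
    test_ds = LabeledDataset.concat(test_parts)
    X_test, _ = _maybe_features(spec, test_ds)

    pools: list[LabeledDataset] = []
    if mode == "new_datasets":
        acc_pool: list[LabeledDataset] = []
        for part in train_parts:
            acc_pool.append(part)
            pools.append(LabeledDataset.concat(list(acc_pool)))
    else:
        full = LabeledDataset.concat(train_parts)
        order = rng.permutation(len(full))
        if step > len(full):
            raise ValueError("step larger than the available training pool")
        sizes = list(range(step, len(full), step)) + [len(full)]
        pools = [full.subset(order[:s]) for s in sizes]

    # for the feature baselines, featurize the full pool once and subset rows
    full_pool = LabeledDataset.concat(train_parts)
    pool_X = pool_y = None
    if spec.kind != "convnet":
        pool_X, pool_y = feature_matrix(full_pool)
        key = {id(r): i for i, r in enumerate(full_pool.rois)}

    rows = []
    for it, pool in enumerate(pools):
        it_seed = int(rng.integers(0, 2**31 - 1))
        if pool_X is not None:
            idx = [key[id(r)] for r in pool.rois]
            model = _fit(spec, pool, it_seed, pool_X[idx], pool_y[idx])
        else:
            model = _fit(spec, pool, it_seed)
        acc = _eval(model, test_ds, X_test)
        rows.append(
            {
                "mode": mode,
                "iteration": it,
                "n_train": len(pool),
                "seed": it_seed,
                "classifier": spec.kind,
                "accuracy": acc,
            }
        )
    return ExperimentResult(
        "learning_curve",
        pd.DataFrame(rows),
        {"mode": mode, "step": step, "test_frac": test_frac, "seed": seed,
         "classifier": spec.kind, "net": spec.net.to_dict() if spec.net else None},
    )


def _random_transform(voxels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = voxels
    if rng.random() < 0.5:
        v = v[::-1]
    if rng.random() < 0.5:
        v = v[:, ::-1]
    if rng.random() < 0.5:
        v = v[:, :, ::-1]
    if rng.random() < 0.5:
        v = v.swapaxes(1, 2)
    return np.ascontiguousarray(v)


def augmentation_curve(
    ds: LabeledDataset,
    spec: ClassifierSpec,
    base: int = 1500,
    step: int = 1500,
    n_steps: int = 3,
    test_frac: float = 0.25,
    seed: int = 0,
) -> ExperimentResult:
    """Adding fresh images versus adding augmented copies of a fixed base.

    Starting from ``base`` training images, each iteration grows the
    training set by ``step`` images: the *fresh* arm draws new images from
    the pool, the *augmented* arm adds random flip/transpose copies of the
    original base images.  Both arms are tested on one fixed held-out set.
    Per-epoch training augmentation is disabled in this protocol, and all
    training runs within one call share a single classifier seed, so the
    arms and iterations form a paired comparison that differs only in
    training-set content.
    """
    rng = np.random.default_rng(seed)
    t_idx, pool_idx = _split_indices(len(ds), test_frac, rng)
    test_ds = ds.subset(sorted(t_idx))
    X_test, _ = _maybe_features(spec, test_ds)
    pool_idx = rng.permutation(pool_idx)
    if base + n_steps * step > len(pool_idx):
        raise ValueError("insufficient data for the fresh-data arm")
    base_ds = ds.subset(pool_idx[:base])

    if spec.kind == "convnet":
        net_cfg = dataclasses.replace(spec.net or NetConfig(), augment=False)
        spec = ClassifierSpec("convnet", net_cfg)

    rows = []
    fit_seed = int(rng.integers(0, 2**31 - 1))
    from .volio import ROI

    for it in range(n_steps + 1):
        n_total = base + it * step
        fresh_ds = ds.subset(pool_idx[:n_total])
        aug_rois = list(base_ds.rois)
        aug_rng = np.random.default_rng(seed + 1000 + it)
        while len(aug_rois) < n_total:
            src = base_ds[int(aug_rng.integers(0, base))]
            aug_rois.append(
                ROI(_random_transform(src.voxels, aug_rng), src.center_zyx, src.label, src.dataset_id)
            )
        aug_ds = LabeledDataset(aug_rois)
        for arm, arm_ds in (("fresh", fresh_ds), ("augmented", aug_ds)):
            if it == 0 and arm == "augmented":
                continue  # identical to the fresh arm at the base point
            model = _fit(spec, arm_ds, fit_seed)
            acc = _eval(model, test_ds, X_test)
            rows.append(
                {
                    "arm": arm if it > 0 else "base",
                    "iteration": it,
                    "n_train": len(arm_ds),
                    "seed": fit_seed,
                    "accuracy": acc,
                }
            )
    return ExperimentResult(
        "augmentation_curve",
        pd.DataFrame(rows),
        {"base": base, "step": step, "n_steps": n_steps, "test_frac": test_frac,
         "seed": seed, "classifier": spec.kind,
         "net": spec.net.to_dict() if spec.net else None},
    )


def transfer_experiment(
    source_datasets: Sequence[LabeledDataset],
    target_ds: LabeledDataset,
    spec: ClassifierSpec,
    train_frac: float = 0.8,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    source_epochs: int | None = None,
) -> ExperimentResult:
    """Three-arm transfer comparison on a second bacterial species.

    Arms, all evaluated on the same held-out 20% of the target data per
    seed: *source_only* (the source-species network applied unchanged),
    *cold_start* (fresh training on the target 80% split), and *transfer*
    (training on the same split warm-started from the source weights).
    """
    if spec.kind != "convnet":
        raise ValueError("transfer learning applies to the convnet classifier")
    base_cfg = spec.net or NetConfig()
    source_pool = LabeledDataset.concat(list(source_datasets))
    src_cfg = dataclasses.replace(
        base_cfg,
        seed=int(seeds[0]) + 7919,
        epochs=source_epochs or base_cfg.epochs,
    )
    source_model = train(build_network(src_cfg), source_pool, src_cfg)

    rows = []
    for s in seeds:
        rng = np.random.default_rng(s)
        tr_idx, te_idx = _split_indices(len(target_ds), train_frac, rng)
        train_split = target_ds.subset(sorted(tr_idx))
        test_split = target_ds.subset(sorted(te_idx))
        cfg = dataclasses.replace(base_cfg, seed=int(s))
        cold = train(build_network(cfg), train_split, cfg)
        warm = transfer_train(source_model, train_split, cfg)
        for arm, model in (
            ("source_only", source_model),
            ("cold_start", cold),
            ("transfer", warm),
        ):
            rows.append(
                {
                    "arm": arm,
                    "seed": int(s),
                    "n_train": 0 if arm == "source_only" else len(train_split),
                    "n_test": len(test_split),
                    "accuracy": _eval(model, test_split),
                }
            )
    return ExperimentResult(
        "transfer_experiment",
        pd.DataFrame(rows),
        {"train_frac": train_frac, "seeds": list(map(int, seeds)),
         "net": base_cfg.to_dict(), "n_source": len(source_pool)},
    )
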