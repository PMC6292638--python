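import dataclasses

import numpy as np
import pytest

from bacfinder.classify import (
    NetConfig,
    augment,
    build_network,
    load_model,
    predict,
    save_model,
    train,
    train_baseline,
    transfer_train,
)
from bacfinder.features import feature_matrix
from bacfinder.synthgen import generate_sanity_dataset
from bacfinder.volio import ROI, ROI_SHAPE, LabeledDataset


class TestBuildNetwork:
    def test_default_shape_trace(self):
        net = build_network()
        assert net.shape_trace() == [
            (8, 28, 28),
            (4, 14, 14),
            (2, 7, 7),
            (1, 4, 4),
            (1, 2, 2),
        ]
        assert net.flat_dim == 128

    def test_default_parameter_count(self):
        """Independent hand arithmetic: conv1 (2*5*5*1*16+16)=816,
        conv2 (2*5*5*16*32+32)=25632, fc (128*1024+1024)=132096,
        out (1024*2+2)=2050; total 160594."""
        net = build_network()
        params = {k: v.size for k, v in net.parameters().items()}
        assert params["W1"] + params["b1"] == 816
        assert params["W2"] + params["b2"] == 25632
        assert params["Wf"] + params["bf"] == 132096
        assert params["Wo"] + params["bo"] == 2050
        assert net.param_count() == 160594

    def test_small_first_layer_count(self):
        net = build_network(NetConfig(kernels_layer1=4))
        assert net.parameters()["W1"].size + net.parameters()["b1"].size == 204

    def test_forward_gives_probabilities(self, rng):
        net = build_network()
        p = net.predict_proba(rng.random((3, 8, 28, 28), dtype=np.float32))
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(dropout=1.5)
        with pytest.raises(ValueError):
            NetConfig(learning_rate=0)


class TestAugment:
    def test_identity_under_noop_rng(self, asymmetric_roi):
        class NoopRng:
            def random(self):
                return 0.9  # never below 0.5 -> no transform applied

        out = augment(asymmetric_roi, NoopRng())
        np.testing.assert_array_equal(out.voxels, asymmetric_roi.voxels)

    def test_flips_are_involutions(self, asymmetric_roi):
        v = asymmetric_roi.voxels
        for ax in range(3):
            np.testing.assert_array_equal(np.flip(np.flip(v, ax), ax), v)

    def test_label_and_multiset_preserved(self, asymmetric_roi, rng):
        out = augment(asymmetric_roi, rng)
        assert out.label == asymmetric_roi.label
        np.testing.assert_array_equal(
            np.sort(out.voxels.ravel()), np.sort(asymmetric_roi.voxels.ravel())
        )

    def test_closure_has_16_elements(self, asymmetric_roi):
        """Composing flips and the lateral transpose reaches exactly 16
        distinct transforms on an asymmetric ROI."""
        v = asymmetric_roi.voxels
        seen = {v.tobytes()}
        frontier = [v]
        while frontier:
            cur = frontier.pop()
            for nxt in (
                cur[::-1],
                cur[:, ::-1],
                cur[:, :, ::-1],
                cur.swapaxes(1, 2),
            ):
                nxt = np.ascontiguousarray(nxt)
                if nxt.tobytes() not in seen:
                    seen.add(nxt.tobytes())
                    frontier.append(nxt)
        assert len(seen) == 16


class TestTrainPredict:
    def test_sanity_task_reaches_perfect_training_accuracy(self, sanity_dataset):
        cfg = NetConfig(epochs=15, learning_rate=3e-4, seed=0)
        model = train(build_network(cfg), sanity_dataset, cfg)
        pred, probs = predict(model, sanity_dataset)
        assert (pred == sanity_dataset.labels).mean() == 1.0
        assert np.all(np.isfinite(model.loss_log))
        assert model.loss_log[-1] < model.loss_log[0]
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_is_deterministic(self, sanity_dataset):
        cfg = NetConfig(epochs=2, seed=1)
        model = train(build_network(cfg), sanity_dataset, cfg)
        p1 = predict(model, sanity_dataset)[1]
        p2 = predict(model, sanity_dataset)[1]
        np.testing.assert_array_equal(p1, p2)

    def test_training_deterministic_given_seed(self, sanity_dataset):
        cfg = NetConfig(epochs=2, seed=7)
        m1 = train(build_network(cfg), sanity_dataset, cfg)
        m2 = train(build_network(cfg), sanity_dataset, cfg)
        np.testing.assert_array_equal(m1.loss_log, m2.loss_log)
        for k, v in m1.model.get_weights().items():
            np.testing.assert_array_equal(v, m2.model.get_weights()[k])

    def test_single_class_rejected(self, rng):
        ds = LabeledDataset(
            [ROI(rng.random(ROI_SHAPE), (4, 14, 14), 1, "f") for _ in range(8)]
        )
        cfg = NetConfig(epochs=1)
        with pytest.raises(ValueError):
            train(build_network(cfg), ds, cfg)
        with pytest.raises(ValueError):
            train_baseline("random_forest", np.zeros((8, 31)), np.ones(8))

    def test_augmented_training_set_keeps_sanity_accuracy(self, sanity_dataset, rng):
        """Replacing each ROI by a random transform of itself does not change
        trainability of the sanity task (label-invariance of augmentation)."""
        aug_ds = LabeledDataset([augment(r, rng) for r in sanity_dataset])
        cfg = NetConfig(epochs=15, learning_rate=3e-4, seed=0)
        model = train(build_network(cfg), aug_ds, cfg)
        pred, _ = predict(model, aug_ds)
        assert (pred == aug_ds.labels).mean() == 1.0


class TestBaselines:
    def test_both_baselines_solve_sanity_task(self, sanity_dataset):
        X, y = feature_matrix(sanity_dataset)
        for kind in ("random_forest", "svm"):
            model = train_baseline(kind, X, y, seed=0)
            pred, _ = predict(model, sanity_dataset)
            assert (pred == y).mean() == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            train_baseline("gradient_boosting", np.zeros((4, 31)), np.array([0, 1, 0, 1]))


class TestTransfer:
    def test_zero_epoch_transfer_predicts_like_source(self, sanity_dataset):
        cfg = NetConfig(epochs=3, seed=0)
        source = train(build_network(cfg), sanity_dataset, cfg)
        frozen = transfer_train(source, sanity_dataset, dataclasses.replace(cfg, epochs=0))
        p_src = predict(source, sanity_dataset)[1]
        p_frz = predict(frozen, sanity_dataset)[1]
        np.testing.assert_array_equal(p_src, p_frz)
        assert frozen.provenance["warm_start"] == "source"

    def test_topology_mismatch_rejected(self, sanity_dataset):
        cfg = NetConfig(epochs=1, seed=0)
        source = train(build_network(cfg), sanity_dataset, cfg)
        bad_cfg = NetConfig(kernels_layer1=8, epochs=1)
        with pytest.raises(ValueError):
            transfer_train(source, sanity_dataset, bad_cfg)


class TestModelIO:
    def test_save_load_roundtrip(self, tmp_path, sanity_dataset):
        cfg = NetConfig(epochs=2, seed=3)
        model = train(build_network(cfg), sanity_dataset, cfg)
        p = tmp_path / "model.npz"
        save_model(model, p)
        back = load_model(p)
        np.testing.assert_array_equal(
            predict(model, sanity_dataset)[1], predict(back, sanity_dataset)[1]
        )
        assert back.provenance["n_train"] == len(sanity_dataset)
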