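import numpy as np
import pytest

from bacfinder.synthgen import (
    SyntheticSpec,
    generate_roi_dataset,
    generate_volume,
    render_capsule,
    species_b_spec,
)
from bacfinder.volio import LABEL_BACTERIUM, LABEL_NOISE


SHAPE = (16, 64, 64)
VS = (1.0, 0.1625, 0.1625)
CENTER = (8.0, 32.0, 32.0)


class TestRenderCapsule:
    def test_zero_length_is_sphere(self):
        f = render_capsule(CENTER, (0, 0, 1), 0.0, 0.7, 10.0, SHAPE, VS)
        # support symmetric in y and x through the center voxel row/col
        ys = np.nonzero(f[8, :, 32])[0]
        xs = np.nonzero(f[8, 32, :])[0]
        assert abs((ys.max() - 32) - (32 - ys.min())) <= 1
        assert len(ys) == len(xs)  # lateral isotropy

    def test_x_axis_rod_extents(self):
        """A 3.25 um rod along +x spans ~length+diameter in x, ~diameter in y.

        Oracle: brute-force distance evaluation says voxels with any
        sub-voxel coverage along the axis row span length + diameter
        (20 + 4.3 voxels in x) and one diameter (4-5 voxels) in y.
        """
        f = render_capsule(CENTER, (0, 0, 1), 3.25, 0.7, 10.0, SHAPE, VS)
        xs = np.nonzero(f[8, 32, :] >= 0.1)[0]
        ys = np.nonzero(f[8, :, 32] >= 0.1)[0]
        assert abs((xs.max() - xs.min() + 1) - 24) <= 1  # 20 + 4 voxels
        assert 4 <= ys.max() - ys.min() + 1 <= 6

    def test_amplitude_linearity(self):
        f1 = render_capsule(CENTER, (1, 1, 1), 2.0, 0.7, 5.0, SHAPE, VS)
        f2 = render_capsule(CENTER, (1, 1, 1), 2.0, 0.7, 10.0, SHAPE, VS)
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-6)

    def test_zero_orientation_rejected(self):
        with pytest.raises(ValueError):
            render_capsule(CENTER, (0, 0, 0), 2.0, 0.7, 1.0, SHAPE, VS)

    def test_longer_rod_has_more_total_intensity(self):
        totals = [
            render_capsule(CENTER, (0, 1, 0), L, 0.7, 10.0, SHAPE, VS).sum()
            for L in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(b > a for a, b in zip(totals, totals[1:]))


class TestGenerateVolume:
    def test_deterministic(self):
        spec = SyntheticSpec(volume_shape_zyx=(16, 96, 96), n_bacteria=3, n_distractors=3, seed=7)
        v1, t1 = generate_volume(spec)
        v2, t2 = generate_volume(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        assert [o.center_zyx for o in t1.objects] == [o.center_zyx for o in t2.objects]

    def test_empty_volume_is_exact_background(self):
        spec = SyntheticSpec(
            volume_shape_zyx=(8, 32, 32),
            n_bacteria=0,
            n_distractors=0,
            read_noise_sd=0.0,
            photon_scale=np.inf,
            background_gradient=10.0,
            organ_level=0.0,
            seed=3,
        )
        vol, truth = generate_volume(spec)
        assert truth.objects == []
        # constant + linear ramp: second differences vanish along each axis
        for ax in range(3):
            d2 = np.diff(vol.data.astype(np.float64), n=2, axis=ax)
            np.testing.assert_allclose(d2, 0, atol=1e-3)

    def test_empty_volume_mean_matches_background_level(self):
        spec = SyntheticSpec(
            volume_shape_zyx=(16, 64, 64),
            n_bacteria=0,
            n_distractors=0,
            background_gradient=0.0,
            organ_level=0.0,
            seed=11,
        )
        vol, _ = generate_volume(spec)
        n = vol.data.size
        voxel_sd = np.sqrt(spec.background_level / spec.photon_scale + spec.read_noise_sd**2)
        se = voxel_sd / np.sqrt(n)
        assert abs(vol.data.mean() - spec.background_level) < 3 * se + 0.05

    def test_ground_truth_counts_and_margins(self):
        spec = SyntheticSpec(seed=2)
        vol, truth = generate_volume(spec)
        bact = [o for o in truth.objects if o.cls == "bacterium"]
        assert len(bact) == spec.n_bacteria
        assert len(truth.objects) == spec.n_bacteria + spec.n_distractors
        vs = np.array(spec.voxel_size_um)
        shape = np.array(spec.volume_shape_zyx)
        for o in bact:
            c = np.array(o.center_zyx)
            margin = np.maximum(o.length_um / vs, 2.0)
            assert (c >= margin - 1e-6).all()
            assert (c <= shape - 1 - margin + 1e-6).all()

    def test_impossible_placement_raises(self):
        spec = SyntheticSpec(
            volume_shape_zyx=(8, 48, 48), n_bacteria=40, n_distractors=0, seed=0
        )
        with pytest.raises(ValueError):
            generate_volume(spec)


class TestGenerateRoiDataset:
    def test_bookkeeping(self):
        spec = SyntheticSpec(seed=0)
        ds = generate_roi_dataset(spec, (10, 10), n_datasets=2, seed=1)
        assert len(ds) == 40
        assert ds.class_counts == {LABEL_NOISE: 20, LABEL_BACTERIUM: 20}
        assert set(ds.dataset_ids) == {"fish0", "fish1"}

    def test_default_class_mix(self):
        ds = generate_roi_dataset(SyntheticSpec(seed=4), (62, 38), n_datasets=1, seed=2)
        counts = ds.class_counts
        assert counts[LABEL_BACTERIUM] == 38
        assert counts[LABEL_NOISE] == 62

    def test_distinct_content_across_seeds(self):
        spec = SyntheticSpec(seed=0)
        d1 = generate_roi_dataset(spec, (5, 5), seed=1)
        d2 = generate_roi_dataset(spec, (5, 5), seed=2)
        all_rois = d1.voxel_array().reshape(10, -1).tolist() + d2.voxel_array().reshape(10, -1).tolist()
        as_tuples = {tuple(r) for r in all_rois}
        assert len(as_tuples) == 20  # no two ROIs identical

    def test_deterministic(self):
        spec = SyntheticSpec(seed=0)
        d1 = generate_roi_dataset(spec, (4, 4), seed=9)
        d2 = generate_roi_dataset(spec, (4, 4), seed=9)
        np.testing.assert_array_equal(d1.voxel_array(), d2.voxel_array())


def test_species_b_is_morphologically_distinct():
    a, b = SyntheticSpec(), species_b_spec()
    assert b.bacterium_length_um[1] < a.bacterium_length_um[1]
    assert b.amplitude_range != a.amplitude_range


def test_less_shot_noise_does_not_hurt_detection_recall():
    """Raising photon_scale (cleaner images) keeps or improves recall (majority of 5 seeds)."""
    from bacfinder.presets import detection_trial

    shape, nb, nd = (48, 192, 192), 12, 15
    wins = 0
    for s in range(5):
        r_noisy, _ = detection_trial(
            s, photon_scale=0.8, volume_shape_zyx=shape, n_bacteria=nb, n_distractors=nd
        )
        r_clean, _ = detection_trial(
            s, photon_scale=20.0, volume_shape_zyx=shape, n_bacteria=nb, n_distractors=nd
        )
        wins += r_clean >= r_noisy
    assert wins >= 3
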