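import numpy as np
import pytest

from bacfinder.blobs import (
    Blob2D,
    detect_blobs_2d,
    dog_responses,
    extract_roi,
    link_blobs,
)
from bacfinder.volio import Volume


def gaussian_spot(shape, cy, cx, s, amp=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))


def brute_force_blobs(img, sigmas, threshold):
    """Exhaustive local-maximum oracle: triple loop over (scale, y, x)."""
    resp = dog_responses(img, sigmas)
    ns, h, w = resp.shape
    found = []
    for s in range(ns):
        for y in range(h):
            for x in range(w):
                v = resp[s, y, x]
                if v <= threshold:
                    continue
                is_max = True
                for ds in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if ds == dy == dx == 0:
                                continue
                            s2, y2, x2 = s + ds, y + dy, x + dx
                            if 0 <= s2 < ns and 0 <= y2 < h and 0 <= x2 < w:
                                if resp[s2, y2, x2] >= v:
                                    is_max = False
                    if not is_max:
                        break
                if is_max:
                    found.append(Blob2D(0, y, x, float(sigmas[s]), float(v)))
    # same overlap pruning rule as the implementation
    found.sort(key=lambda b: -b.response)
    kept = []
    for b in found:
        if all(
            (b.y - k.y) ** 2 + (b.x - k.x) ** 2 >= 2 * max(b.sigma, k.sigma) ** 2
            for k in kept
        ):
            kept.append(b)
    return kept


SIGMAS = (1.0, 1.6, 2.56, 4.096)


class TestDogResponses:
    def test_constant_slice_zero_response(self):
        resp = dog_responses(np.full((32, 32), 9.0), SIGMAS)
        np.testing.assert_allclose(resp, 0, atol=1e-10)

    def test_linearity(self, rng):
        img = rng.random((24, 24))
        np.testing.assert_allclose(
            dog_responses(3 * img, SIGMAS), 3 * dog_responses(img, SIGMAS), atol=1e-9
        )

    def test_scale_selection_matches_closed_form(self):
        """The ladder argmax matches the analytic DoG response of a Gaussian spot.

        A Gaussian spot of scale s blurred by G(sigma) keeps amplitude
        s^2/(s^2+sigma^2), so the center response of level i is
        sigma_i*(s^2/(s^2+sigma_i^2) - s^2/(s^2+sigma_{i+1}^2)) * amp.
        """
        for s in (1.3, 2.0, 3.2):
            img = gaussian_spot((64, 64), 32, 32, s)
            resp = dog_responses(img, SIGMAS)
            analytic = [
                SIGMAS[i]
                * (s**2 / (s**2 + SIGMAS[i] ** 2) - s**2 / (s**2 + SIGMAS[i + 1] ** 2))
                * 100.0
                for i in range(len(SIGMAS) - 1)
            ]
            assert resp[:, 32, 32].argmax() == int(np.argmax(analytic))
            np.testing.assert_allclose(resp[:, 32, 32], analytic, rtol=0.02)

    def test_requires_two_increasing_sigmas(self):
        with pytest.raises(ValueError):
            dog_responses(np.zeros((8, 8)), [1.0])
        with pytest.raises(ValueError):
            dog_responses(np.zeros((8, 8)), [2.0, 1.0])


class TestDetectBlobs2D:
    def test_flat_slice_empty(self):
        assert detect_blobs_2d(np.zeros((32, 32)), SIGMAS, threshold=1.0) == []

    def test_two_spots_found_at_centers(self):
        img = gaussian_spot((64, 64), 20, 12, 1.8) + gaussian_spot((64, 64), 20, 52, 1.8)
        blobs = detect_blobs_2d(img, SIGMAS, threshold=5.0)
        assert len(blobs) == 2
        centers = sorted((b.y, b.x) for b in blobs)
        for found, true in zip(centers, [(20, 12), (20, 52)]):
            assert abs(found[0] - true[0]) <= 1 and abs(found[1] - true[1]) <= 1

    def test_threshold_monotonicity(self):
        img = gaussian_spot((64, 64), 20, 12, 1.8) + gaussian_spot((64, 64), 20, 52, 1.8)
        assert detect_blobs_2d(img, SIGMAS, threshold=1e6) == []

    def test_mask_restricts_detections(self):
        img = gaussian_spot((64, 64), 20, 12, 1.8) + gaussian_spot((64, 64), 20, 52, 1.8)
        mask = np.zeros((64, 64), bool)
        mask[:, :32] = True
        blobs = detect_blobs_2d(img, SIGMAS, threshold=5.0, mask=mask)
        assert len(blobs) == 1 and blobs[0].x < 32

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(4):
            img = rng.random((48, 48)) * 10
            for _ in range(rng.integers(1, 4)):
                img += gaussian_spot(
                    (48, 48), rng.integers(6, 42), rng.integers(6, 42), rng.uniform(1.2, 3.0)
                )
            got = detect_blobs_2d(img, SIGMAS, threshold=3.0)
            want = brute_force_blobs(img, SIGMAS, 3.0)
            assert {(b.y, b.x, b.sigma) for b in got} == {(b.y, b.x, b.sigma) for b in want}

    def test_translation_equivariance(self):
        base = gaussian_spot((64, 64), 24, 24, 1.8)
        shifted = gaussian_spot((64, 64), 29, 21, 1.8)
        b0 = detect_blobs_2d(base, SIGMAS, threshold=5.0)
        b1 = detect_blobs_2d(shifted, SIGMAS, threshold=5.0)
        assert (b1[0].y - b0[0].y, b1[0].x - b0[0].x) == (5, -3)


class TestLinkBlobs:
    def test_vertical_chain(self):
        per_slice = [[Blob2D(z, 10, 10, 1.6, 5.0 + z)] for z in range(3)]
        cands = link_blobs(per_slice, min_chain=1)
        assert len(cands) == 1
        assert cands[0].chain_length == 3
        assert cands[0].center_zyx == (2, 10, 10)  # max-response member
        assert cands[0].response == 7.0

    def test_gap_breaks_chain(self):
        per_slice = [[Blob2D(0, 10, 10, 1.6, 5.0)], [], [Blob2D(2, 10, 10, 1.6, 5.0)]]
        cands = link_blobs(per_slice, min_chain=1)
        assert len(cands) == 2

    def test_min_chain_filters(self):
        per_slice = [[Blob2D(0, 10, 10, 1.6, 5.0)], [], [Blob2D(2, 30, 30, 1.6, 5.0)]]
        assert link_blobs(per_slice, min_chain=2) == []

    def test_lateral_distance_limit(self):
        per_slice = [[Blob2D(0, 10, 10, 1.6, 5.0)], [Blob2D(1, 10, 30, 1.6, 5.0)]]
        cands = link_blobs(per_slice, max_lateral_dist=3.0, min_chain=1)
        assert len(cands) == 2

    def test_synthetic_bacteria_recovered(self):
        """Detection+linking on a small synthetic volume matches ground truth."""
        from bacfinder.blobs import detect_volume
        from bacfinder.presets import score_detection
        from bacfinder.synthgen import SyntheticSpec, generate_volume

        spec = SyntheticSpec(
            volume_shape_zyx=(32, 128, 128), n_bacteria=5, n_distractors=0, seed=42
        )
        vol, truth = generate_volume(spec)
        cands = detect_volume(vol)
        recall, precision = score_detection(cands, truth, vol.voxel_size_um)
        assert recall == 1.0


class TestExtractRoi:
    def test_interior_constant(self):
        v = Volume(np.full((16, 64, 64), 7.0))
        roi = extract_roi(v, (8, 32, 32))
        assert roi.voxels.shape == (8, 28, 28)
        assert (roi.voxels == 7).all()

    def test_corner_zero_padded(self):
        v = Volume(np.full((16, 64, 64), 7.0))
        roi = extract_roi(v, (0, 0, 0))
        assert roi.voxels[4, 14, 14] == 7  # center voxel
        assert roi.voxels[0, 0, 0] == 0  # out-of-bounds padding
        assert (roi.voxels[:4] == 0).all()
        assert (roi.voxels[:, :14] == 0).all()

    def test_matches_direct_slicing(self, rng):
        v = Volume(rng.random((16, 64, 64)) * 100)
        for _ in range(20):
            cz = int(rng.integers(4, 12))
            cy = int(rng.integers(14, 50))
            cx = int(rng.integers(14, 50))
            roi = extract_roi(v, (cz, cy, cx))
            np.testing.assert_array_equal(
                roi.voxels, v.data[cz - 4 : cz + 4, cy - 14 : cy + 14, cx - 14 : cx + 14]
            )
            assert roi.center_zyx == (cz, cy, cx)

    def test_center_outside_rejected(self):
        v = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            extract_roi(v, (10, 0, 0))
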