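"""SURF stage contracts: integral image, Hessian responses, detection,
orientation and descriptors."""

import numpy as np
import pytest

import pisurf as ps
from pisurf.surf import (
    BorderError,
    DetectorParams,
    build_scale_space,
    detect_keypoints,
    hessian_response,
    integral_image,
    octave_filter_sizes,
)

import _oracles as oracle
from conftest import blob_image, random_image


class TestIntegralImage:
    def test_all_ones_cumulative(self):
        ii = integral_image(np.ones((3, 3)))
        assert ii.table[3, 3] == 9.0
        assert ii.table[0, :].tolist() == [0, 0, 0, 0]

    def test_single_pixel(self):
        assert integral_image(np.array([[0.7]])).table[1, 1] == pytest.approx(0.7)

    def test_every_rectangle_matches_loop_sums_exactly(self):
        # 8-bit-quantized values: all partial sums are exact in float64,
        # so the 4-lookup identity must hold with zero error
        img = random_image(13, (16, 16), levels=256)
        ii = integral_image(img)
        for top in range(16):
            for left in range(16):
                for h in range(1, 16 - top + 1):
                    for w in range(1, 16 - left + 1):
                        assert ps.box_sum(ii, top, left, h, w) == oracle.rect_sum_loop(
                            img, top, left, h, w
                        )

    def test_box_sum_clipping(self):
        ii = integral_image(np.ones((4, 4)))
        assert ps.box_sum(ii, 0, 0, 4, 4) == 16.0
        assert ps.box_sum(ii, -5, -5, 3, 3) == 0.0
        assert ps.box_sum(ii, 10, 10, 2, 2) == 0.0
        assert ps.box_sum(ii, -1, -1, 3, 3) == 4.0
        with pytest.raises(ValueError):
            ps.box_sum(ii, 0, 0, 0, 2)

    def test_random_rectangles_with_clipping(self):
        img = random_image(17, (20, 15))
        ii = integral_image(img)
        rng = np.random.default_rng(4)
        for _ in range(50):
            top, left = rng.integers(-6, 22, 2)
            h, w = rng.integers(1, 12, 2)
            assert ps.box_sum(ii, top, left, h, w) == pytest.approx(
                oracle.rect_sum_loop(img, top, left, h, w), abs=1e-12
            )


class TestHessianResponse:
    def test_constant_image_is_zero(self):
        # second derivatives of a constant vanish; only cumsum rounding remains
        ii = integral_image(np.full((40, 40), 0.6))
        assert np.allclose(hessian_response(ii, 9), 0.0, atol=1e-12)
        ii_dyadic = integral_image(np.full((40, 40), 0.5))
        assert np.all(hessian_response(ii_dyadic, 9) == 0.0)

    def test_invalid_filter_sizes(self):
        ii = integral_image(np.zeros((40, 40)))
        for bad in (8, 7, 11, 12):
            with pytest.raises(ValueError):
                hessian_response(ii, bad)

    def test_single_pixel_ninety_degree_symmetry(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        resp = hessian_response(integral_image(img), 9)
        assert np.allclose(resp, np.rot90(resp), atol=1e-12)

    def test_blob_argmax_near_center(self):
        img = blob_image([(32, 32)], [4.0], shape=(64, 64))
        resp = hessian_response(integral_image(img), 27)  # sigma=3.6, best for blob 4
        y, x = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(y - 32) <= 1 and abs(x - 32) <= 1

    def test_border_is_zero_where_filter_does_not_fit(self):
        img = random_image(3, (40, 40))
        resp = hessian_response(integral_image(img), 15)
        m = 7
        assert np.all(resp[:m, :] == 0) and np.all(resp[:, :m] == 0)
        assert np.all(resp[-m:, :] == 0) and np.all(resp[:, -m:] == 0)
        assert np.any(resp[m:-m, m:-m] != 0)


class TestScaleSpace:
    def test_canonical_progression(self):
        assert octave_filter_sizes(0, 4) == [9, 15, 21, 27]
        assert octave_filter_sizes(1, 4) == [15, 27, 39, 51]
        assert octave_filter_sizes(2, 4) == [27, 51, 75, 99]
        assert octave_filter_sizes(3, 4) == [51, 99, 147, 195]

    def test_bookkeeping_on_paper_sized_image(self):
        ss = build_scale_space(integral_image(random_image(0, (181, 217))))
        assert ss.octaves == 4 and ss.levels_per_octave == 4
        assert sum(len(m) for m in ss.maps) == 16
        assert ss.filter_sizes[0] == [9, 15, 21, 27]
        assert ss.scales[0][0] == pytest.approx(1.2)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_scale_space(integral_image(np.ones((5, 5))))


class TestDetection:
    def test_constant_image_no_keypoints(self):
        ss = build_scale_space(integral_image(np.full((64, 64), 0.4)))
        assert detect_keypoints(ss, 1e-4) == []

    def test_three_separated_blobs_found(self):
        centers = [(24, 24), (24, 72), (72, 48)]
        img = blob_image(centers, [4.0, 5.0, 6.0], shape=(96, 96))
        kps = detect_keypoints(build_scale_space(integral_image(img)), 1e-4)
        for cy, cx in centers:
            assert min(np.hypot(k.x - cx, k.y - cy) for k in kps) <= 2.0

    @pytest.mark.parametrize("sigma", [3, 4, 6, 8])
    def test_single_blob_center_and_oracle_argmax(self, sigma):
        img = blob_image([(48, 48)], [sigma], shape=(96, 96))
        kps = detect_keypoints(build_scale_space(integral_image(img)), 1e-4)
        assert kps, f"no detection for blob sigma={sigma}"
        top = kps[0]
        assert np.hypot(top.x - 48, top.y - 48) <= 2.0
        oy, ox = oracle.gaussian_hessian_argmax(img, [1.2, 2.0, 2.8, 3.6, 5.2, 6.8])
        assert np.hypot(top.x - ox, top.y - oy) <= 1.0

    def test_detected_points_beat_their_26_neighbours(self):
        img = ps.make_phantom(ps.PhantomSpec(seed=5, noise_sigma=0.0))
        ss = build_scale_space(integral_image(img))
        kps = detect_keypoints(ss, 1e-4)
        assert kps
        # re-check a handful of raw maxima directly on the response maps
        checked = 0
        for kp in kps[:20]:
            xi, yi = int(round(kp.x)), int(round(kp.y))
            for o in range(ss.octaves):
                for k in range(1, ss.levels_per_octave - 1):
                    m = ss.maps[o][k]
                    if abs(m[yi, xi] - kp.response) / max(abs(kp.response), 1e-12) < 0.5:
                        cube = np.stack(
                            [lvl[yi - 1 : yi + 2, xi - 1 : xi + 2] for lvl in
                             (ss.maps[o][k - 1], m, ss.maps[o][k + 1])]
                        )
                        if m[yi, xi] >= cube.max():
                            assert np.sum(cube >= m[yi, xi]) == 1
                            checked += 1
        assert checked >= 5

    def test_translation_equivariance(self):
        img = ps.make_phantom(ps.PhantomSpec(seed=8, noise_sigma=0.0, shape=(128, 128)))
        shifted = np.roll(img, (6, 9), axis=(0, 1))
        kp0 = detect_keypoints(build_scale_space(integral_image(img)), 5e-4)
        kp1 = detect_keypoints(build_scale_space(integral_image(shifted)), 5e-4)
        interior = [
            k for k in kp0
            if 20 <= k.x < 128 - 30 and 20 <= k.y < 128 - 30
        ]
        assert interior
        moved = 0
        for k in interior:
            d = min(np.hypot(q.x - (k.x + 9), q.y - (k.y + 6)) for q in kp1)
            if d <= 0.5:
                moved += 1
        assert moved / len(interior) >= 0.9

    def test_determinism(self, phantom):
        a = detect_keypoints(build_scale_space(integral_image(phantom)), 1e-4)
        b = detect_keypoints(build_scale_space(integral_image(phantom)), 1e-4)
        assert a == b

    def test_all_keypoints_inside_and_above_threshold(self, phantom):
        kps = detect_keypoints(build_scale_space(integral_image(phantom)), 1e-4)
        h, w = phantom.shape
        for k in kps:
            assert 0 <= k.x < w and 0 <= k.y < h
            assert k.scale > 0
            assert k.response > 1e-4


class TestOrientationAndDescriptor:
    def test_orientation_range_and_determinism(self, phantom):
        ii = integral_image(phantom)
        kps = detect_keypoints(build_scale_space(ii), 1e-4)
        from pisurf.surf import assign_orientation

        k = next(k for k in kps if 40 < k.x < 170 and 40 < k.y < 140)
        a = assign_orientation(ii, k)
        b = assign_orientation(ii, k)
        assert a.orientation == b.orientation
        assert 0 <= a.orientation < 2 * np.pi

    def test_rotation_equivariance_of_orientation(self):
        img = ps.make_phantom(ps.PhantomSpec(seed=21, noise_sigma=0.0, shape=(129, 129)))
        rot = np.rot90(img).copy()
        kps0, _ = ps.extract(img)
        kps1, _ = ps.extract(rot)
        n = img.shape[0]
        agreements = []
        for k in kps0[:30]:
            # rot90 (counter-clockwise): (x, y) -> (y, n-1-x)
            tx, ty = k.y, n - 1 - k.x
            near = [q for q in kps1 if np.hypot(q.x - tx, q.y - ty) < 1.5]
            if not near:
                continue
            q = min(near, key=lambda q: np.hypot(q.x - tx, q.y - ty))
            # with y down, (x, y) -> (y, n-1-x) turns gradients by -90 deg
            diff = np.rad2deg((q.orientation - k.orientation) % (2 * np.pi))
            agreements.append(min(abs(diff - 270), abs(diff - 270 + 360)))
        assert agreements
        assert np.median(agreements) <= 10.0

    def test_descriptor_unit_norm(self, phantom):
        _, desc = ps.extract(phantom)
        assert desc
        for d in desc:
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-6)

    def test_descriptor_translation_stability(self):
        img = ps.make_phantom(ps.PhantomSpec(seed=31, noise_sigma=0.0, shape=(128, 128)))
        shifted = np.roll(img, (0, 5), axis=(0, 1))
        k0, d0 = ps.extract(img)
        k1, d1 = ps.extract(shifted)
        tested = 0
        for k, d in zip(k0, d0):
            if not (30 <= k.x < 90 and 30 <= k.y < 98):
                continue
            cands = [
                (np.hypot(q.x - (k.x + 5), q.y - k.y), e) for q, e in zip(k1, d1)
            ]
            dist, e = min(cands, key=lambda c: c[0])
            if dist <= 1.0:
                assert np.linalg.norm(d - e) < 0.3
                tested += 1
        assert tested >= 3

    def test_descriptor_contrast_invariance(self):
        # a positive affine intensity map cancels exactly in the Haar
        # differences and the unit normalization
        img = ps.make_phantom(ps.PhantomSpec(seed=41, noise_sigma=0.0))
        ii0 = integral_image(img)
        ii1 = integral_image(0.1 + 0.6 * img)
        kps, _ = ps.extract(img)
        assert len(kps) >= 10
        for k in kps[:15]:
            d0 = ps.compute_descriptor(ii0, k)
            d1 = ps.compute_descriptor(ii1, k)
            assert np.linalg.norm(d0 - d1) < 1e-3

    def test_border_keypoint_rejected(self, phantom):
        from pisurf.surf import Keypoint, assign_orientation

        ii = integral_image(phantom)
        with pytest.raises(BorderError):
            assign_orientation(ii, Keypoint(x=2.0, y=2.0, scale=2.0))
        with pytest.raises(BorderError):
            ps.compute_descriptor(ii, Keypoint(x=3.0, y=3.0, scale=2.0))


class TestExtract:
    def test_constant_image_empty(self):
        kps, desc = ps.extract(np.full((64, 64), 0.2))
        assert kps == [] and desc == []

    def test_too_small_image(self):
        with pytest.raises(ValueError):
            ps.extract(np.ones((30, 30)))

    def test_determinism_and_count(self, phantom):
        k1, d1 = ps.extract(phantom)
        k2, d2 = ps.extract(phantom)
        assert k1 == k2
        assert all(np.array_equal(a, b) for a, b in zip(d1, d2))
        assert len(k1) >= 20

    def test_ordering(self, phantom):
        kps, _ = ps.extract(phantom)
        keys = [(-k.response, k.y, k.x) for k in kps]
        assert keys == sorted(keys)
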