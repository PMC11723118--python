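"""Gaussian heatmap / cross-tensor encoders, pooling algebra, decoding."""

import numpy as np
import pytest

from larvapose.annotations import KeypointSet
from larvapose.errors import DataError
from larvapose.targets import (CrossHeatTensor, HeatmapSpec, decode_heatmap,
                               decode_keypoints, make_anisotropic_heatmap,
                               make_cross_tensor_gt, make_isotropic_heatmap,
                               pool_heatmap_to_cross, reconstruct_heatmap)

SIZE = (32, 24)  # heatmap (W, H)


def _kps_at(x, y, n=26):
    xy = np.tile([x, y], (n, 1))
    return KeypointSet.from_array(xy)


class TestHeatmapEncoders:
    def test_peak_is_one_at_gt_pixel(self):
        kps = _kps_at(40.0, 44.0)  # -> heatmap pixel (10, 11)
        hm = make_isotropic_heatmap(kps, HeatmapSpec(3, 3, 4), SIZE)
        assert hm.values[0, 11, 10] == 1.0
        assert hm.values.max() == 1.0

    def test_value_at_sigma_offset(self):
        kps = _kps_at(40.0, 44.0)
        hm = make_isotropic_heatmap(kps, HeatmapSpec(3, 3, 4), SIZE)
        # one sigma along x: exp(-sigma^2 / (2 sigma^2)) = exp(-1/2)
        assert hm.values[0, 11, 13] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_zero_outside_three_sigma(self):
        kps = _kps_at(40.0, 44.0)
        hm = make_isotropic_heatmap(kps, HeatmapSpec(3, 3, 4), SIZE)
        assert hm.values[0, 11, 10 + 10] == 0.0  # beyond the 3-sigma box
        assert hm.values[0, 11, 10 + 9] > 0.0    # |dx| = 3 sigma is included

    def test_anisotropic_equals_isotropic_when_sigmas_match(self, random_keypoints):
        spec = HeatmapSpec(3, 3, 4)
        a = make_isotropic_heatmap(random_keypoints, spec, SIZE)
        b = make_anisotropic_heatmap(random_keypoints, spec, SIZE)
        assert np.array_equal(a.values, b.values)

    def test_anisotropic_axis_value(self):
        # the (3, 2) configuration at an x offset of 3 heatmap px: exp(-1/2)
        kps = _kps_at(40.0, 44.0)
        hm = make_anisotropic_heatmap(kps, HeatmapSpec(3, 2, 4), SIZE)
        assert hm.values[0, 11, 13] == pytest.approx(np.exp(-0.5), abs=1e-12)
        # along y the sigma is 2, so 2 px off gives exp(-1/2)
        assert hm.values[0, 13, 10] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_iso_level_sets_are_axis_aligned_ellipses(self):
        kps = _kps_at(40.0, 44.0, n=26)
        hm = make_anisotropic_heatmap(kps, HeatmapSpec(4, 2, 4), SIZE)
        level = np.exp(-0.5)
        row = hm.values[0, 11, :]
        col = hm.values[0, :, 10]
        # semi-axes at this level are sigma_x and sigma_y -> ratio 2
        x_extent = np.flatnonzero(row >= level - 1e-9)
        y_extent = np.flatnonzero(col >= level - 1e-9)
        assert (x_extent.max() - x_extent.min()) == 2 * (y_extent.max() - y_extent.min())

    def test_monotone_decrease_inside_support(self):
        kps = _kps_at(40.0, 44.0)
        hm = make_isotropic_heatmap(kps, HeatmapSpec(3, 3, 4), SIZE)
        row = hm.values[0, 11, 10:19]
        assert np.all(np.diff(row) < 0)

    def test_out_of_bounds_keypoint_named(self):
        xy = np.tile([40.0, 44.0], (26, 1))
        xy[4] = [500.0, 44.0]
        with pytest.raises(DataError, match="keypoint 5"):
            make_isotropic_heatmap(KeypointSet.from_array(xy), HeatmapSpec(3, 3, 4), SIZE)


class TestCrossTensor:
    def test_vector_values(self):
        ct = make_cross_tensor_gt(_kps_at(40.0, 44.0), SIZE, sigma=1.0)
        assert ct.width_vectors[0, 10] == 1.0
        assert ct.width_vectors[0, 11] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert ct.width_vectors[0, 14] == 0.0  # beyond 3 sigma
        assert ct.height_vectors[0, 11] == 1.0

    def test_outer_product_matches_separable_heatmap(self, random_keypoints):
        sigma = 2.0
        ct = make_cross_tensor_gt(random_keypoints, SIZE, sigma=sigma)
        hm = make_isotropic_heatmap(random_keypoints, HeatmapSpec(sigma, sigma, 4), SIZE)
        outer = reconstruct_heatmap(ct).values
        # inside the joint 3-sigma support the products agree exactly
        joint = (hm.values > 0)
        np.testing.assert_allclose(outer[joint], hm.values[joint], atol=1e-12)

    def test_pool_of_rank_one_map_is_proportional(self, rng):
        u = rng.uniform(0.1, 1.0, SIZE[1])
        v = rng.uniform(0.1, 1.0, SIZE[0])
        u /= u.max()
        v /= v.max()
        from larvapose.targets import HeatmapStack

        stack = HeatmapStack((u[:, None] * v[None, :])[None], 4)
        ct = pool_heatmap_to_cross(stack)
        np.testing.assert_allclose(ct.width_vectors[0], v, atol=1e-7)
        np.testing.assert_allclose(ct.height_vectors[0], u, atol=1e-7)

    def test_pool_zero_map_flagged(self):
        from larvapose.targets import HeatmapStack

        ct = pool_heatmap_to_cross(HeatmapStack(np.zeros((2, 8, 8)), 4))
        assert ct.zero_channels.all()
        assert not ct.width_vectors.any()

    def test_pool_reconstruct_exact_for_rank_one_peak_one(self, random_keypoints):
        hm = reconstruct_heatmap(make_cross_tensor_gt(random_keypoints, SIZE))
        back = reconstruct_heatmap(pool_heatmap_to_cross(hm))
        np.testing.assert_allclose(back.values, hm.values, atol=1e-7)

    def test_reconstruction_is_rank_one(self, random_keypoints):
        hm = reconstruct_heatmap(make_cross_tensor_gt(random_keypoints, SIZE))
        for k in range(0, 26, 5):
            s = np.linalg.svd(hm.values[k], compute_uv=False)
            assert s[1] <= 1e-10 * max(s[0], 1.0)

    def test_pooled_argmax_matches_map_argmax(self, rng):
        for _ in range(20):
            xy = np.tile(rng.uniform(12, 80, 2), (26, 1))
            hm = make_isotropic_heatmap(KeypointSet.from_array(xy),
                                        HeatmapSpec(2, 2, 4), SIZE)
            ct = pool_heatmap_to_cross(hm)
            r, c = np.unravel_index(hm.values[0].argmax(), hm.values[0].shape)
            assert ct.width_vectors[0].argmax() == c
            assert ct.height_vectors[0].argmax() == r


class TestDecoding:
    def test_encode_decode_round_trip_1000_random(self, rng):
        stride = 4
        errs = []
        for _ in range(40):  # 40 draws x 26 keypoints > 1000 round trips
            # stay clear of the last half-stride so quantization stays in-map
            xy = np.column_stack([rng.uniform(0, SIZE[0] * stride - 3, 26),
                                  rng.uniform(0, SIZE[1] * stride - 3, 26)])
            kps = KeypointSet.from_array(xy)
            dec = decode_keypoints(make_cross_tensor_gt(kps, SIZE, 1.0, stride))
            errs.append(np.abs(dec.to_array() - xy).max())
        assert max(errs) <= 1 * stride  # one heatmap pixel x stride

    def test_flat_vector_tie_breaks_to_zero(self):
        ct = CrossHeatTensor(np.ones((1, 8)), np.ones((1, 6)), 4)
        dec = decode_keypoints(ct)
        assert dec.to_array()[0].tolist() == [0.0, 0.0]

    def test_refinement_reduces_error_on_continuous_gaussian(self, rng):
        # sampled (unquantized) 1-D Gaussians at 1000 random sub-pixel offsets
        stride, n = 1, 1000
        grid = np.arange(64, dtype=float)
        err_raw = err_ref = 0.0
        for _ in range(n):
            c = rng.uniform(20, 40)
            vec = np.exp(-((grid - c) ** 2) / 2.0)
            ct = CrossHeatTensor(vec[None], vec[None], stride)
            raw = decode_keypoints(ct, refine=False).to_array()[0, 0]
            ref = decode_keypoints(ct, refine=True).to_array()[0, 0]
            err_raw += abs(raw - c)
            err_ref += abs(ref - c)
        assert err_ref < err_raw

    def test_heatmap_decode_round_trip(self, random_keypoints):
        hm = make_isotropic_heatmap(random_keypoints, HeatmapSpec(2, 2, 4), SIZE)
        dec = decode_heatmap(hm)
        assert np.abs(dec.to_array() - random_keypoints.to_array()).max() <= 4.0
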