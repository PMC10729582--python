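"""Vessel enhancement and segmentation: oracles, analytic cases, invariants."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from gliavasc.exceptions import DegenerateDistributionError
from gliavasc.synthetic import render_tubes
from gliavasc.vessels import (
    FrangiParams,
    HysteresisThresholds,
    frangi_vesselness,
    hessian_eigenvalues,
    hysteresis_segment,
    otsu3_thresholds,
    segment_vessels,
)
from oracles import hysteresis_floodfill, otsu3_bruteforce


class TestHessianEigenvalues:
    def test_constant_image_has_zero_curvature(self):
        eigs = hessian_eigenvalues(np.full((16, 16), 7.0), scale=1.0)
        assert np.allclose(eigs, 0.0, atol=1e-10)

    def test_separable_quadratic_recovers_analytic_hessian(self):
        # f(x, y) = x^2 has Hessian diag(2, 0) away from the boundary
        x = np.arange(32, dtype=float)
        img = np.broadcast_to(x**2, (32, 32)).copy()
        eigs = hessian_eigenvalues(img.T, scale=1.0, normalize=False)
        interior = (slice(8, 24), slice(8, 24))
        assert np.allclose(eigs[0][interior], 0.0, atol=1e-6)
        assert np.allclose(eigs[1][interior], 2.0, atol=1e-6)

    def test_matches_finite_difference_eigendecomposition(self, rng):
        img = gaussian_filter(rng.normal(size=(32, 32)), 2.0)
        scale = 1.5
        eigs = hessian_eigenvalues(img, scale)
        sm = gaussian_filter(img, scale, mode="reflect")
        gy, gx = np.gradient(sm)
        hyy, hyx = np.gradient(gy)
        hxy, hxx = np.gradient(gx)
        H = np.stack(
            [np.stack([hyy, 0.5 * (hyx + hxy)], -1),
             np.stack([0.5 * (hyx + hxy), hxx], -1)], -2
        )
        ref = np.linalg.eigvalsh(H) * scale**2  # ascending by value
        ref_sorted = np.take_along_axis(
            np.moveaxis(ref, -1, 0), np.argsort(np.abs(np.moveaxis(ref, -1, 0)), axis=0), axis=0
        )
        assert np.allclose(eigs, ref_sorted, rtol=1e-6, atol=1e-9)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            hessian_eigenvalues(np.zeros((8, 8)), scale=0.0)


class TestFrangiVesselness:
    def test_constant_image_gives_zero_map(self):
        v = frangi_vesselness(np.full((24, 24), 3.0))
        assert np.all(v == 0.0)

    def test_range_and_offset_invariance(self, rng):
        img = rng.uniform(0, 100, size=(32, 32))
        v1 = frangi_vesselness(img)
        v2 = frangi_vesselness(img + 50.0)
        assert v1.min() >= 0.0 and v1.max() <= 1.0
        assert np.allclose(v1, v2, atol=1e-9)

    def test_rotation_equivariance(self, rng):
        img = gaussian_filter(rng.uniform(0, 100, size=(32, 32)), 1.0)
        assert np.allclose(
            frangi_vesselness(np.rot90(img)), np.rot90(frangi_vesselness(img)), atol=1e-8
        )

    def test_tube_centerline_beats_background(self):
        # straight tube radius 2 px through a 2D image
        shape, vs = (48, 64), (1.0, 1.0)
        line = np.array([[24.0, 0.0], [24.0, 63.0]])
        img, mask = render_tubes([line], [2.0], shape, vs)
        v = frangi_vesselness(img)
        centerline = v[24, 8:56]
        background = v[24 + 8, 8:56]  # 2 radii outside the tube wall
        assert centerline.min() > background.max()

    def test_tube_outscores_equal_contrast_blob(self):
        shape, vs = (64, 64), (1.0, 1.0)
        line = np.array([[32.0, 0.0], [32.0, 63.0]])
        tube_img, _ = render_tubes([line], [2.0], shape, vs)
        yy, xx = np.mgrid[:64, :64]
        blob_img = 200.0 * np.exp(-((yy - 32.0) ** 2 + (xx - 32.0) ** 2) / (2 * 2.0**2))
        v_tube = frangi_vesselness(tube_img)[32, 32]
        v_blob = frangi_vesselness(blob_img)[32, 32]
        assert v_blob < v_tube


class TestOtsu3:
    def test_three_pure_classes_are_separated(self):
        values = np.repeat([0.0, 0.5, 1.0], 100)
        thr = otsu3_thresholds(values)
        assert 0.0 < thr.low <= 0.5 < thr.high <= 1.0

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            otsu3_thresholds(np.full(100, 0.7))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1, size=10_000)
        thr = otsu3_thresholds(values)
        low, high = otsu3_bruteforce(values)
        assert thr.low == pytest.approx(low, abs=1e-12)
        assert thr.high == pytest.approx(high, abs=1e-12)

    def test_equals_bruteforce_on_trimodal_mixture(self, rng):
        values = np.concatenate(
            [rng.normal(0.2, 0.03, 400), rng.normal(0.5, 0.03, 300), rng.normal(0.8, 0.03, 300)]
        )
        thr = otsu3_thresholds(values)
        low, high = otsu3_bruteforce(values)
        assert (thr.low, thr.high) == pytest.approx((low, high), abs=1e-12)


class TestHysteresis:
    def test_all_below_low_gives_empty_mask(self):
        v = np.full((8, 8), 0.1)
        mask = hysteresis_segment(v, HysteresisThresholds(0.5, 0.9))
        assert not mask.any()

    def test_single_strong_voxel_recruits_whole_component(self):
        v = np.zeros((16, 16))
        v[4:8, 4:12] = 0.4
        v[5, 6] = 0.95
        mask = hysteresis_segment(v, HysteresisThresholds(0.3, 0.9))
        assert np.array_equal(mask, v > 0.3)

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            HysteresisThresholds(0.9, 0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_floodfill_on_random_volumes(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = rng.uniform(0, 1, size=(16, 16, 16))
        mask = hysteresis_segment(v, HysteresisThresholds(0.6, 0.9))
        assert np.array_equal(mask, hysteresis_floodfill(v, 0.6, 0.9))

    def test_lowering_low_never_shrinks_mask(self, rng):
        v = rng.uniform(0, 1, size=(32, 32))
        hi = 0.9
        bigger = hysteresis_segment(v, HysteresisThresholds(0.3, hi))
        smaller = hysteresis_segment(v, HysteresisThresholds(0.6, hi))
        assert np.all(bigger[smaller])


class TestSegmentVessels:
    def test_blank_channel_gives_empty_mask(self):
        seg = segment_vessels(np.zeros((16, 16)))
        assert not seg.mask.any()

    def test_mask_respects_hysteresis_invariants(self, clean_fov):
        seg = segment_vessels(clean_fov.clean_channels["vessel"])
        assert np.all(seg.vesselness[seg.mask] > seg.thresholds.low)

    def test_noise_free_network_dice(self, clean_fov):
        from gliavasc.evaluate import dice

        seg = segment_vessels(clean_fov.clean_channels["vessel"])
        assert dice(seg.mask, clean_fov.truth.vessel_mask) >= 0.8

    def test_noise_shifts_dice_by_less_than_a_tenth(self, clean_fov, noisy_fov):
        from gliavasc.evaluate import dice

        truth = clean_fov.truth.vessel_mask
        d_clean = dice(segment_vessels(clean_fov.clean_channels["vessel"]).mask, truth)
        d_noisy = dice(segment_vessels(noisy_fov.channels["vessel"]).mask, truth)
        assert abs(d_clean - d_noisy) < 0.1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FrangiParams(gamma_fraction=1.5)
        with pytest.raises(ValueError):
            FrangiParams(scales=())
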