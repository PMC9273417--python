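"""Log-domain retinex identities and oracle equivalences."""

import numpy as np
import pytest

from wbcseg.retinex import (
    RetinexParams,
    SurroundScaleSet,
    color_recovery_constant,
    gaussian_surround,
    msr,
    msrcr,
    reflectance_stack,
    ssr,
    stretch_to_display,
)

from conftest import brute_force_conv_reflect


class TestGaussianSurround:
    def test_normalised_and_symmetric(self):
        for sigma in (1.0, 5.0):
            k = gaussian_surround(sigma)
            assert k.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(k, k.T, atol=1e-15)
            np.testing.assert_allclose(k, k[::-1, ::-1], atol=1e-15)

    def test_matches_direct_evaluation(self):
        sigma, truncate = 2.0, 4.0
        k = gaussian_surround(sigma, truncate)
        radius = int(truncate * sigma + 0.5)
        xs = np.arange(-radius, radius + 1)
        direct = np.exp(-(xs[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2))
        direct /= direct.sum()
        np.testing.assert_allclose(k, direct, atol=1e-14)
        assert k[radius, radius] == pytest.approx(direct[radius, radius])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_surround(0.0)


class TestSSR:
    def test_constant_plane_zero_reflectance(self):
        plane = np.full((16, 16), 0.3)
        assert np.abs(ssr(plane, 3.0)).max() < 1e-6

    def test_near_identity_kernel(self, rng):
        # with a very small surround the blur is nearly the identity
        plane = 0.1 + 0.8 * rng.random((12, 12))
        assert np.abs(ssr(plane, 0.05, 0.0)).max() < 1e-6

    def test_matches_brute_force_convolution(self, rng):
        plane = rng.random((8, 8))
        sigma, eps = 2.0, 1.0 / 255.0
        kernel = gaussian_surround(sigma)
        expected = np.log(plane + eps) - np.log(
            brute_force_conv_reflect(plane, kernel) + eps)
        np.testing.assert_allclose(ssr(plane, sigma, eps), expected, atol=1e-6)

    def test_multichannel_rejected(self, rng):
        with pytest.raises(Exception):
            ssr(rng.random((8, 8, 3)), 2.0)

    def test_decomposition_identity(self, rng):
        plane = rng.random((16, 16))
        stack = reflectance_stack(plane, 4.0)
        np.testing.assert_allclose(stack.s - stack.l, stack.r, atol=1e-6)

    def test_illumination_invariance(self, rng):
        # multiplying the plane by a constant leaves the reflectance unchanged
        plane = 0.05 + 0.9 * rng.random((64, 64))
        for c in (0.25, 3.0):
            r1 = ssr(plane, 5.0, 0.0)
            r2 = ssr(c * plane, 5.0, 0.0)
            assert np.abs(r1 - r2).max() < 1e-4


class TestMSR:
    def test_single_scale_degenerates_to_ssr(self, rng):
        plane = rng.random((10, 10))
        s = SurroundScaleSet.single(3.0)
        np.testing.assert_allclose(msr(plane, s), ssr(plane, 3.0), atol=1e-12)

    def test_constant_plane_zero(self):
        assert np.abs(msr(np.full((20, 20), 0.6))).max() < 1e-6

    def test_equal_weights_are_arithmetic_mean(self, rng):
        plane = rng.random((16, 16))
        surround = SurroundScaleSet(scales=(2.0, 4.0, 8.0))
        mean = np.mean([ssr(plane, s) for s in surround.scales], axis=0)
        np.testing.assert_allclose(msr(plane, surround), mean, atol=1e-9)

    def test_scale_set_validation(self):
        with pytest.raises(ValueError):
            SurroundScaleSet(scales=(5.0, 2.0), weights=(0.5, 0.5))
        with pytest.raises(ValueError):
            SurroundScaleSet(scales=(1.0, 2.0), weights=(0.9, 0.9))


class TestColorRecovery:
    def test_equal_channels(self):
        v = 0.4
        assert color_recovery_constant(v, 3 * v) == pytest.approx(46 * np.log(125 / 3))

    def test_unit_log_argument_is_zero(self):
        # value/sum = 1/beta makes the log argument exactly 1
        assert color_recovery_constant(1.0, 125.0) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_oracle(self):
        got = color_recovery_constant(0.7, 1.5, alpha=46.0, beta=125.0)
        assert got == pytest.approx(46.0 * np.log(125.0 * 0.7 / 1.5), rel=1e-12)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError):
            color_recovery_constant(0.5, 0.0)


class TestStretch:
    def test_minmax_endpoints(self):
        out = stretch_to_display(np.array([[-1.0, 0.0, 1.0]]))
        np.testing.assert_allclose(out, [[0.0, 127.5, 255.0]], atol=1e-9)

    def test_constant_plane_mid_grey(self):
        out = stretch_to_display(np.full((5, 5), 3.7))
        np.testing.assert_allclose(out, 128.0)

    def test_percentile_matches_sort_oracle(self, rng):
        plane = rng.normal(size=(40, 40))
        p_lo, p_hi = 1.0, 99.0
        flat = np.sort(plane.ravel())

        def quantile(q):
            pos = q / 100.0 * (flat.size - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, flat.size - 1)
            return flat[lo] + (pos - lo) * (flat[hi] - flat[lo])

        lo, hi = quantile(p_lo), quantile(p_hi)
        clipped = np.clip(plane, lo, hi)
        expected = (clipped - lo) / (hi - lo) * 255.0
        got = stretch_to_display(plane, ("percentile", p_lo, p_hi))
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            stretch_to_display(np.zeros((2, 2)), "sigmoid")


class TestMSRCR:
    def test_flat_image_stays_flat(self):
        img = np.full((16, 16, 3), 0.42)
        out = msrcr(img).pixels
        assert np.ptp(out) < 1e-9
        assert out.flat[0] == pytest.approx(128.0)

    def test_staged_brute_force_composition(self, rng):
        img = 0.05 + 0.9 * rng.random((16, 16, 3))
        params = RetinexParams(surround=SurroundScaleSet(scales=(2.0, 5.0),
                                                         weights=(0.5, 0.5)))
        eps = params.log_eps_unit
        expected = np.empty_like(img)
        channel_sum = np.maximum(img.sum(axis=2), eps)
        for i in range(3):
            f = np.zeros(img.shape[:2])
            for sigma, w in zip(params.surround.scales, params.surround.weights):
                kernel = gaussian_surround(sigma)
                blur = brute_force_conv_reflect(img[:, :, i], kernel)
                f += w * (np.log(img[:, :, i] + eps) - np.log(blur + eps))
            c = params.alpha * np.log(
                np.maximum(params.beta_const * img[:, :, i] / channel_sum, eps))
            expected[:, :, i] = stretch_to_display(c * f, params.stretch)
        got = msrcr(img, params).pixels
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_output_spans_display_range(self, rng):
        out = msrcr(rng.random((16, 16, 3))).pixels
        for i in range(3):
            assert out[:, :, i].min() == pytest.approx(0.0, abs=1e-9)
            assert out[:, :, i].max() == pytest.approx(255.0, abs=1e-9)

    def test_non_rgb_rejected(self, rng):
        with pytest.raises(Exception):
            msrcr(rng.random((8, 8)))
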