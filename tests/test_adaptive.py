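"""Block-adaptive colour recovery: contrast, gain and pipeline properties."""

import numpy as np
import pytest

from wbcseg.adaptive import (
    adaptive_beta,
    adaptive_color_recovery,
    adaptive_retinex_correct,
    component_histogram,
    michelson_contrast,
    partition_blocks,
    to_hsv,
    to_rgb,
)
from wbcseg.image import RasterImage
from wbcseg.retinex import RetinexParams, SurroundScaleSet
from wbcseg.synthetic import SmearConfig, generate_smear, rasterize_objects


class TestColourConversion:
    @pytest.mark.parametrize("rgb, hsv", [
        ((1.0, 0.0, 0.0), (0.0, 1.0, 1.0)),
        ((128 / 255,) * 3, (0.0, 0.0, 128 / 255)),
    ])
    def test_reference_colours(self, rgb, hsv):
        img = np.full((2, 2, 3), rgb)
        got = to_hsv(img).pixels[0, 0]
        np.testing.assert_allclose(got, hsv, atol=1e-12)

    def test_round_trip_within_byte_quantum(self, rng):
        img = rng.random((16, 16, 3))
        back = to_rgb(to_hsv(img)).pixels
        assert np.abs(back - img).max() <= 1.0 / 255.0

    def test_non_rgb_rejected(self, rng):
        with pytest.raises(Exception):
            to_hsv(rng.random((4, 4)))


class TestPartition:
    def test_exact_tiling(self, rng):
        grid = partition_blocks(rng.random((64, 64)), 32)
        assert grid.n == 4
        assert all(b.row_span[1] - b.row_span[0] == 32 for b in grid.blocks)

    def test_truncated_border_blocks(self, rng):
        grid = partition_blocks(rng.random((70, 70)), 32)
        assert grid.n == 9
        last = grid.blocks[-1]
        assert last.row_span == (64, 70) and last.col_span == (64, 70)

    def test_degenerate_single_block(self, rng):
        grid = partition_blocks(rng.random((10, 10)), 100)
        assert grid.n == 1
        assert grid.blocks[0].row_span == (0, 10)

    def test_blocks_tile_without_overlap(self, rng):
        plane = rng.random((50, 37))
        grid = partition_blocks(plane, 16)
        cover = np.zeros(plane.shape, dtype=int)
        for b in grid.blocks:
            cover[b.row_span[0]:b.row_span[1], b.col_span[0]:b.col_span[1]] += 1
        assert (cover == 1).all()

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            partition_blocks(rng.random((8, 8)), 0)


class TestMichelsonContrast:
    @pytest.mark.parametrize("pixels, expected", [
        (np.full((4, 4), 0.5), 0.0),       # I_max = I_min -> C_M = 0
        (np.array([1.0, 0.0]), 1.0),       # full contrast
        (np.array([3.0, 1.0, 2.0]), 0.5),  # (3-1)/(3+1)
        (np.zeros((3, 3)), 0.0),           # all-black convention
    ])
    def test_cases(self, pixels, expected):
        assert michelson_contrast(pixels) == pytest.approx(expected)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            michelson_contrast(np.array([]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            michelson_contrast(np.array([-0.1, 0.5]))


class TestAdaptiveBeta:
    def test_zero_contrast_gives_gamma(self):
        assert adaptive_beta(0.0, 125.0) == pytest.approx(125.0)

    def test_full_contrast_gives_gamma_e(self):
        assert adaptive_beta(1.0, 125.0) == pytest.approx(125.0 * np.e)

    def test_scalar_oracle(self):
        assert adaptive_beta(0.5, 100.0) == pytest.approx(100.0 * np.exp(0.5))

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range_contrast_rejected(self, bad):
        with pytest.raises(ValueError):
            adaptive_beta(bad, 125.0)

    def test_beta_range_and_monotonicity(self, rng):
        # every block's beta lies in [gamma, gamma*e]; raising a block's
        # contrast never lowers its beta
        plane = rng.random((48, 48))
        grid = partition_blocks(plane, 16, gamma=125.0)
        for b in grid.blocks:
            assert 125.0 - 1e-9 <= b.beta <= 125.0 * np.e + 1e-9
            assert b.beta == pytest.approx(125.0 * np.exp(b.c_m))
        bumped = plane.copy()
        bumped[0, 0] = 1.0  # raises block (0,0) contrast
        grid2 = partition_blocks(bumped, 16, gamma=125.0)
        assert grid2.blocks[0].beta >= grid.blocks[0].beta


class TestAdaptiveColorRecovery:
    def test_constant_blocks_reduce_to_constant_gain(self, rng):
        # blockwise-constant plane: every C_M = 0, so the adaptive gain equals
        # the classic colour-recovery function with beta = gamma
        coarse = rng.random((4, 4))
        plane = np.kron(coarse, np.ones((8, 8)))
        total = np.full_like(plane, 1.5)
        grid = partition_blocks(plane, 8, gamma=125.0)
        got = adaptive_color_recovery(plane, total, grid, alpha=46.0, gamma=125.0)
        expected = 46.0 * np.log(np.maximum(125.0 * plane / total, 1e-8))
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_single_block_staged_oracle(self):
        plane = np.array([[0.2, 0.4], [0.6, 0.8]])
        total = np.array([[1.0, 1.2], [1.4, 1.6]])
        grid = partition_blocks(plane, 4, gamma=100.0)
        c_m = (0.8 - 0.2) / (0.8 + 0.2)
        beta = 100.0 * np.exp(c_m)
        expected = 46.0 * np.log(beta * plane / total)
        got = adaptive_color_recovery(plane, total, grid, alpha=46.0, gamma=100.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_doubling_gamma_shifts_by_alpha_log2(self, rng):
        plane = 0.1 + 0.8 * rng.random((16, 16))
        total = np.full_like(plane, 1.2)
        grid = partition_blocks(plane, 8, gamma=125.0)
        base = adaptive_color_recovery(plane, total, grid, alpha=46.0, gamma=125.0)
        doubled = adaptive_color_recovery(plane, total, grid, alpha=46.0, gamma=250.0)
        np.testing.assert_allclose(doubled - base, 46.0 * np.log(2.0), atol=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        grid = partition_blocks(rng.random((16, 16)), 8)
        with pytest.raises(ValueError):
            adaptive_color_recovery(rng.random((8, 8)), rng.random((8, 8)), grid)


class TestComponentHistogram:
    def test_constant_plane_single_bin(self):
        stats = component_histogram(np.full((10, 10), 0.35), bins=10)
        assert stats.histogram.sum() == 100
        assert (stats.histogram > 0).sum() == 1

    def test_ramp_matches_direct_binning(self):
        plane = np.linspace(0.0, 1.0, 100).reshape(10, 10)
        stats = component_histogram(plane, bins=4)
        expected, _ = np.histogram(plane, bins=4, range=(0.0, 1.0))
        np.testing.assert_array_equal(stats.histogram, expected)


class TestAdaptiveCorrection:
    def test_flat_image_stays_flat(self):
        img = np.full((32, 32, 3), 0.6)
        out = adaptive_retinex_correct(img).pixels
        assert np.ptp(out.reshape(-1, 3), axis=0).max() < 1e-9

    def test_blockwise_constant_reduces_to_constant_beta(self, rng):
        # on a per-block-constant image the adaptive and the constant-beta(=gamma)
        # paths coincide
        params = RetinexParams(surround=SurroundScaleSet(scales=(2.0, 6.0),
                                                         weights=(0.5, 0.5)),
                               block_k=8)
        coarse = rng.random((4, 4, 3)) * 0.8 + 0.1
        img = np.kron(coarse, np.ones((8, 8))[:, :, None])
        adaptive = adaptive_retinex_correct(img, params).pixels
        constant = adaptive_retinex_correct(img, params,
                                            constant_beta=params.gamma).pixels
        np.testing.assert_allclose(adaptive, constant, atol=1e-6)

    def test_shape_preserved(self, small_smear):
        img, _, _ = small_smear
        out = adaptive_retinex_correct(img)
        assert out.shape == img.shape

    def test_background_v_variance_decreases(self):
        cfg = SmearConfig(illumination=("linear", 0.45), seed=42)
        img, mask, meta = generate_smear(cfg)
        corrected = adaptive_retinex_correct(img).to_unit()
        bg = ~mask & ~rasterize_objects(mask.shape, meta["objects"], "distractor")
        v_raw = to_hsv(img).pixels[:, :, 2]
        v_cor = to_hsv(corrected).pixels[:, :, 2]
        assert v_cor[bg].var() < v_raw[bg].var()

    def test_saturation_contrast_not_decreased(self):
        # correction must not erode the leukocyte-vs-distractor S separation:
        # across gradient-illuminated fixtures the mean separation does not
        # decrease and it is preserved per image in a clear majority
        raw_seps, cor_seps = [], []
        for s in range(10):
            cfg = SmearConfig(illumination=("linear", 0.45), seed=40 + s)
            img, mask, meta = generate_smear(cfg)
            corrected = adaptive_retinex_correct(img).to_unit()
            dist = rasterize_objects(mask.shape, meta["objects"],
                                     "distractor") & ~mask
            s_raw = to_hsv(img).pixels[:, :, 1]
            s_cor = to_hsv(corrected).pixels[:, :, 1]
            raw_seps.append(abs(s_raw[mask].mean() - s_raw[dist].mean()))
            cor_seps.append(abs(s_cor[mask].mean() - s_cor[dist].mean()))
        assert np.mean(cor_seps) >= np.mean(raw_seps)
        wins = sum(c >= r for c, r in zip(cor_seps, raw_seps))
        assert wins >= 8
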