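"""Metric definitions vs brute-force oracles; aggregation; display window."""

import math

import numpy as np
import pytest
from scipy.signal import convolve2d

import cyclect as cc
from cyclect.metrics import SSIMParams


def brute_psnr(f, f0, max_val):
    mse = np.mean((np.asarray(f, float) - np.asarray(f0, float)) ** 2)
    return 10 * math.log10(max_val ** 2 / mse)


def brute_nmad(f, f0):
    return np.sum(np.abs(f - f0)) / np.sum(np.abs(f))


def brute_ssim(f, f0, data_range, win=11, sigma=1.5, k1=0.01, k2=0.03):
    """Windowed SSIM from first principles: explicit Gaussian kernel,
    explicit local moments, border cropped to valid windows only."""
    ax = np.arange(win) - win // 2
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    kern = np.outer(g, g)
    kern /= kern.sum()

    def filt(img):
        return convolve2d(img, kern, mode="valid")

    f, f0 = np.asarray(f, float), np.asarray(f0, float)
    mu1, mu2 = filt(f), filt(f0)
    s11 = filt(f * f) - mu1 ** 2
    s22 = filt(f0 * f0) - mu2 ** 2
    s12 = filt(f * f0) - mu1 * mu2
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    ssim_map = ((2 * mu1 * mu2 + c1) * (2 * s12 + c2)
                / ((mu1 ** 2 + mu2 ** 2 + c1) * (s11 + s22 + c2)))
    return ssim_map.mean()


class TestPSNR:
    def test_identical_images_give_infinity(self):
        a = np.random.default_rng(0).random((16, 16))
        assert cc.psnr(a, a.copy()) == math.inf

    def test_mse_equal_to_max_squared_gives_zero_db(self):
        f0 = np.zeros((8, 8))
        f = np.full((8, 8), 100.0)
        assert cc.psnr(f, f0, max_val=100.0) == pytest.approx(0.0)

    def test_tenth_of_range_gives_20db(self):
        f0 = np.zeros((8, 8))
        f = np.full((8, 8), 10.0)
        assert cc.psnr(f, f0, max_val=100.0) == pytest.approx(20.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        f, f0 = rng.random((12, 12)), rng.random((12, 12))
        assert cc.psnr(f, f0) == pytest.approx(cc.psnr(f0, f))


class TestNMAD:
    def test_identical_zero(self):
        a = np.random.default_rng(0).random((8, 8)) + 1
        assert cc.nmad(a, a.copy()) == 0.0

    def test_double_gives_half(self):
        f0 = np.random.default_rng(1).random((8, 8)) + 1.0
        assert cc.nmad(2 * f0, f0) == pytest.approx(0.5)

    def test_denominator_is_first_argument(self):
        # intentional asymmetry of the printed definition
        rng = np.random.default_rng(2)
        f, f0 = rng.random((8, 8)) + 1, rng.random((8, 8)) + 2
        assert cc.nmad(f, f0) != pytest.approx(cc.nmad(f0, f))
        assert cc.nmad(f, f0, normalize_by_reference=True) == pytest.approx(
            np.sum(np.abs(f - f0)) / np.sum(np.abs(f0)))

    def test_all_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cc.nmad(np.zeros((4, 4)), np.ones((4, 4)))


class TestSSIM:
    def test_identical_images_give_one(self):
        a = np.random.default_rng(0).random((32, 32)) * 2000
        assert cc.ssim(a, a.copy()) == pytest.approx(1.0)

    def test_monotone_under_increasing_noise(self):
        rng = np.random.default_rng(1)
        base = 1000 + 300 * rng.random((64, 64))
        small = cc.ssim(base + rng.normal(0, 20, base.shape), base)
        large = cc.ssim(base + rng.normal(0, 200, base.shape), base)
        assert large < small <= 1.0

    def test_constant_shift_luminance_closed_form(self):
        mu1, c = 1000.0, 150.0
        mu2 = mu1 + c
        f = np.full((32, 32), mu1)
        f0 = np.full((32, 32), mu2)
        c1 = (0.01 * 2000) ** 2
        expect = (2 * mu1 * mu2 + c1) / (mu1 ** 2 + mu2 ** 2 + c1)
        assert cc.ssim(f, f0) == pytest.approx(expect, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        f, f0 = 2000 * rng.random((32, 32)), 2000 * rng.random((32, 32))
        assert cc.ssim(f, f0) == pytest.approx(cc.ssim(f0, f), rel=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            cc.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            f = 2000 * rng.random((24, 24))
            f0 = np.clip(f + rng.normal(0, 120, f.shape), 0, 2000)
            assert cc.psnr(f, f0, 2000) == pytest.approx(
                brute_psnr(f, f0, 2000), rel=1e-8)
            assert cc.nmad(f, f0) == pytest.approx(brute_nmad(f, f0), rel=1e-8)
            assert cc.ssim(f, f0) == pytest.approx(
                brute_ssim(f, f0, 2000), rel=1e-8)
            assert cc.ssim(f, f0) <= 1.0


class TestEvaluate:
    def test_reference_against_itself_is_perfect(self):
        ref = [np.random.default_rng(i).random((32, 32)) * 2000 for i in range(4)]
        rep = cc.evaluate({"self": [r.copy() for r in ref]}, ref)
        with pytest.warns(UserWarning):   # infinite PSNR excluded from means
            s = rep.methods[0].summary()
        assert s["SSIM"] == (1.0, 0.0)
        assert s["NMAD"] == (0.0, 0.0)

    def test_noisier_method_ranks_below(self):
        rng = np.random.default_rng(0)
        ref = [1000 + 200 * rng.random((32, 32)) for _ in range(3)]
        noisy = [r + rng.normal(0, 100, r.shape) for r in ref]
        less = [r + rng.normal(0, 10, r.shape) for r in ref]
        rep = cc.evaluate({"noisy": noisy, "less_noisy": less}, ref)
        by = {m.name: m.summary() for m in rep.methods}
        assert by["less_noisy"]["PSNR"][0] > by["noisy"]["PSNR"][0]
        assert len(rep.methods) == 2

    def test_misaligned_rejected(self):
        ref = [np.zeros((16, 16))] * 3
        with pytest.raises(ValueError):
            cc.evaluate({"m": [np.zeros((16, 16))] * 2}, ref)

    def test_report_table_layout(self):
        ref = [1000 + np.random.default_rng(0).random((32, 32))] * 2
        outs = [r + 5 for r in ref]
        text = cc.evaluate({"ldct": outs}, ref).to_text()
        assert "PSNR" in text and "SSIM" in text and "NMAD" in text
        assert "ldct" in text and "±" in text


class TestDisplayWindow:
    def test_endpoints_map_to_0_and_255(self):
        s = cc.CTSlice(pixels=np.array([[800.0, 1300.0], [800.0, 1300.0]]))
        out = cc.apply_display_window(s, 800, 1300)
        assert out.dtype == np.uint8
        assert out[0, 0] == 0 and out[0, 1] == 255

    def test_midpoint_rounds_half_to_even(self):
        s = cc.CTSlice(pixels=np.full((2, 2), 1050.0))  # maps to exactly 127.5
        assert cc.apply_display_window(s, 800, 1300)[0, 0] == 128

    def test_clipping_outside_window(self):
        s = cc.CTSlice(pixels=np.array([[0.0, 2000.0], [799.9, 1300.1]]))
        out = cc.apply_display_window(s, 800, 1300)
        assert out[0, 0] == 0 and out[0, 1] == 255

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            cc.apply_display_window(cc.CTSlice(pixels=np.zeros((2, 2))), 10, 10)
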