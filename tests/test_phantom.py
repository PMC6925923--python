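"""Simulator: phantom generation, Radon projection, dose noise, FBP."""

import numpy as np
import pytest

import cyclect as cc
from cyclect.datatypes import PhantomImage, SinogramSet


class TestGeneratePhantom:
    def test_degenerate_counts_give_background_ellipse_only(self):
        ph = cc.generate_phantom(seed=0, size=64, n_soft_ellipses=0,
                                 n_bone_features=0)
        assert ph.pixels.shape == (64, 64)
        labels = set(np.unique(ph.structure_mask))
        assert PhantomImage.BONE not in labels
        assert PhantomImage.GAP not in labels
        assert PhantomImage.SOFT in labels

    def test_same_seed_bit_identical(self):
        a = cc.generate_phantom(7, 128, 5, 2)
        b = cc.generate_phantom(7, 128, 5, 2)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.structure_mask, b.structure_mask)

    def test_different_seeds_differ(self):
        a = cc.generate_phantom(7, 64, 5, 2)
        b = cc.generate_phantom(8, 64, 5, 2)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_attenuation_nonnegative_and_mask_complete(self):
        ph = cc.generate_phantom(3, 96, 4, 2)
        assert np.all(ph.pixels >= 0)
        assert ph.structure_mask.shape == ph.pixels.shape
        # hallucination probe present: bone with a narrow gap
        assert (ph.structure_mask == PhantomImage.BONE).any()
        assert (ph.structure_mask == PhantomImage.GAP).any()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            cc.generate_phantom(0, size=16)


class TestForwardProject:
    def test_zero_phantom_gives_zero_sinogram(self):
        ph = cc.generate_phantom(0, 64, 0, 0)
        ph.pixels[:] = 0.0
        sino = cc.forward_project(ph, n_angles=30)
        assert np.allclose(sino.projections, 0.0)

    def test_centered_disk_rotation_symmetric(self):
        size = 65
        yy, xx = np.mgrid[0:size, 0:size]
        c = size // 2       # the projection's rotation center
        disk = 0.2 * (((yy - c) ** 2 + (xx - c) ** 2) < 15 ** 2)
        ph = PhantomImage(pixels=disk, size=size, seed=0,
                          structure_mask=np.zeros_like(disk, dtype=np.uint8))
        sino = cc.forward_project(ph, n_angles=45)
        profiles = sino.projections
        ref = profiles[0]
        dists = np.linalg.norm(profiles - ref, axis=1) / np.linalg.norm(ref)
        assert dists.max() < 0.06   # hard-edge discretization tolerance

    def test_central_bright_pixel_peaks_centrally(self):
        size = 65
        pix = np.zeros((size, size))
        pix[32, 32] = 1.0
        ph = PhantomImage(pixels=pix, size=size, seed=0,
                          structure_mask=np.zeros((size, size), dtype=np.uint8))
        sino = cc.forward_project(ph, n_angles=36)
        peaks = np.argmax(sino.projections, axis=1)
        assert np.all(np.abs(peaks - size // 2) <= 1)

    def test_too_few_angles_rejected(self):
        ph = cc.generate_phantom(0, 64)
        with pytest.raises(ValueError):
            cc.forward_project(ph, n_angles=1)


class TestApplyDoseNoise:
    def test_infinite_photon_limit_is_noiseless(self):
        ph = cc.generate_phantom(1, 64, 2, 1)
        sino = cc.forward_project(ph, n_angles=30, incident_counts=1e12)
        noisy = cc.apply_dose_noise(sino, 1.0, seed=0)
        nz = sino.projections > 0.1
        rel = np.abs(noisy.projections[nz] - sino.projections[nz]) / sino.projections[nz]
        assert rel.max() < 1e-4

    def test_variance_scales_inverse_with_dose(self):
        # flat sinogram p=1: var of -ln(N/lam) ~ 1/lam, so 5% dose has ~20x
        # the variance of 100% dose
        n = 20000
        flat = np.full((2, n), 1.0)
        sino = SinogramSet(projections=flat, angles=np.array([0.0, 90.0]),
                           incident_counts=1e5)
        v_full = np.var(cc.apply_dose_noise(sino, 1.0, 0).projections)
        v_low = np.var(cc.apply_dose_noise(sino, 0.05, 1).projections)
        assert v_low / v_full == pytest.approx(20.0, rel=0.1)

    def test_variance_matches_first_order_theory(self):
        # var(-ln N/lam) ~ 1/lam with lam = d * I0 * exp(-p)
        n = 20000
        p = 0.7
        sino = SinogramSet(projections=np.full((2, n), p),
                           angles=np.array([0.0, 90.0]), incident_counts=1e4)
        for d in (1.0, 0.25, 0.05):
            lam = d * 1e4 * np.exp(-p)
            v = np.var(cc.apply_dose_noise(sino, d, 3).projections)
            assert v == pytest.approx(1.0 / lam, rel=0.1)

    def test_same_seed_reproducible(self):
        ph = cc.generate_phantom(1, 64)
        sino = cc.forward_project(ph, n_angles=30)
        a = cc.apply_dose_noise(sino, 0.05, seed=42)
        b = cc.apply_dose_noise(sino, 0.05, seed=42)
        np.testing.assert_array_equal(a.projections, b.projections)
        assert a.dose_fraction == 0.05

    def test_invalid_dose_rejected(self):
        ph = cc.generate_phantom(1, 64)
        sino = cc.forward_project(ph, n_angles=30)
        with pytest.raises(ValueError):
            cc.apply_dose_noise(sino, 0.0, seed=0)


class TestFBPReconstruct:
    def test_noiseless_disk_reconstruction_accurate(self):
        size = 64
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        disk = 0.2 * (((yy - c) ** 2 + (xx - c) ** 2) < 18 ** 2)
        ph = PhantomImage(pixels=disk, size=size, seed=0,
                          structure_mask=np.zeros_like(disk, dtype=np.uint8))
        sino = cc.forward_project(ph, n_angles=360)
        rec = cc.fbp_reconstruct(sino, "ramp", ct_scale=False)
        interior = ((yy - c) ** 2 + (xx - c) ** 2) < 14 ** 2
        rel_rmse = (np.sqrt(np.mean((rec.pixels[interior] - 0.2) ** 2)) / 0.2)
        assert rel_rmse < 0.05

    def test_zero_sinogram_gives_zero_image(self):
        sino = SinogramSet(projections=np.zeros((30, 64)),
                           angles=np.linspace(0, 180, 30, endpoint=False),
                           incident_counts=1e5)
        rec = cc.fbp_reconstruct(sino, "ramp", ct_scale=False)
        assert np.allclose(rec.pixels, 0.0)

    def test_low_dose_noisier_than_full_dose(self):
        ph = cc.generate_phantom(5, 64, 0, 0)
        sino = cc.forward_project(ph, n_angles=90, incident_counts=2.2e4)
        rec_full = cc.fbp_reconstruct(cc.apply_dose_noise(sino, 1.0, 0))
        rec_low = cc.fbp_reconstruct(cc.apply_dose_noise(sino, 0.05, 0))
        # uniform ROI at the phantom center
        roi = (slice(24, 40), slice(24, 40))
        assert np.var(rec_low.pixels[roi]) > np.var(rec_full.pixels[roi])

    def test_linearity(self):
        ph = cc.generate_phantom(2, 64, 3, 1)
        sino = cc.forward_project(ph, n_angles=45)
        rec1 = cc.fbp_reconstruct(sino, ct_scale=False).pixels
        sino.projections *= 2.5
        rec2 = cc.fbp_reconstruct(sino, ct_scale=False).pixels
        np.testing.assert_allclose(rec2, 2.5 * rec1, atol=1e-10)

    def test_unknown_filter_rejected(self):
        ph = cc.generate_phantom(1, 64)
        sino = cc.forward_project(ph, n_angles=30)
        with pytest.raises(ValueError):
            cc.fbp_reconstruct(sino, "hann")


def test_simulated_collection_contract(sim_small):
    low, ref = sim_small
    assert len(low) == len(ref) == 8
    for i, (s, r) in enumerate(zip(low, ref)):
        assert s.id == i and r.id == i
        assert s.dose_fraction == 0.05 and r.dose_fraction == 1.0
        assert s.provenance == "simulated"
        assert s.pixels.shape == (32, 32)
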