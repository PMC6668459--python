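"""EPRY phase retrieval, the reconstruction residual, and blind refocusing."""

from __future__ import annotations

import numpy as np
import pytest

import platefpm as pf
from platefpm.geometry import GeometryError
from platefpm.metrics import calibrate_star_threshold
from platefpm.pupil import defocus_phase
from platefpm.reconstruct import ReconConfig, ReconstructionError


def truth_spectrum(obj: pf.ComplexObject) -> np.ndarray:
    n = obj.n
    return np.fft.fftshift(np.fft.fft2(obj.values)) / (n * n)


class TestEpryFixedPoint:
    def test_truth_is_a_fixed_point(self, star_object, ideal_pupil, star_dataset, cfg):
        r = pf.epry_reconstruct(
            star_dataset,
            init_pupil=ideal_pupil,
            rc=ReconConfig(n_iters=1, upsample=cfg.upsample),
            init_spectrum=truth_spectrum(star_object),
        )
        assert r.residuals[0] < 1e-10
        assert np.allclose(r.object.values, star_object.values, atol=1e-8)

    def test_noise_free_convergence_below_1e6(self, cfg, brightfield_k):
        # smaller tile so a deep run stays fast
        small = pf.OpticalConfig(tile_um=25.6)
        n_hi = small.tile_px * small.upsample
        px = small.object_pixel_um / small.upsample
        obj = pf.cell_phantom(extent_um=n_hi * px, pixel_um=px, seed=0)
        pup = pf.Pupil.for_config(small.tile_px, small)
        ds = pf.forward_fpm(obj, pup, brightfield_k, small)
        r = pf.epry_reconstruct(ds, rc=ReconConfig(n_iters=300, upsample=4))
        assert r.residuals[-1] < 1e-6
        # residual trace decreases monotonically on consistent data
        assert np.all(np.diff(r.residuals) < 1e-6)

    def test_too_few_frames_rejected(self, star_object, ideal_pupil, cfg):
        ds = pf.forward_fpm(star_object, ideal_pupil, np.zeros((4, 2)), cfg)
        with pytest.raises(GeometryError, match="9 frames"):
            pf.epry_reconstruct(ds, rc=ReconConfig(upsample=cfg.upsample))

    def test_nan_data_aborts_with_iteration_index(self, star_dataset, cfg):
        bad = pf.FPMDataset(star_dataset.frames.copy(), star_dataset.k_eff, cfg, {})
        bad.frames[0, 3, 3] = np.nan
        with pytest.raises(ReconstructionError, match="epoch"):
            pf.epry_reconstruct(bad, rc=ReconConfig(n_iters=2, upsample=cfg.upsample))


class TestPupilRecovery:
    def test_astigmatic_pupil_recovered_below_point1_rad(self, star_object, ideal_pupil, brightfield_k, cfg):
        """0.8 rad of injected astigmatism must come back with piston-removed
        wavefront RMS below 0.1 rad (noise-free parameter recovery)."""
        rho, theta = ideal_pupil.rho_theta()
        z6 = pf.zernike_basis([6], rho, theta)[0]
        true_pupil = ideal_pupil.with_extra_phase(0.8 * z6)
        ds = pf.forward_fpm(star_object, true_pupil, brightfield_k, cfg)
        r = pf.epry_reconstruct(ds, rc=ReconConfig(n_iters=150, upsample=cfg.upsample))
        assert pf.rms_wavefront_diff(r.pupil, true_pupil) < 0.1
        rec = pf.fit_zernike(r.pupil.phase(unwrap=True), rho, theta, 15, unwrap=False)
        assert rec[6] == pytest.approx(0.8, abs=0.15)

    def test_adaptive_steps_keep_residuals_monotone_on_noisy_data(self, star_object, ideal_pupil, brightfield_k, cfg):
        ds = pf.forward_fpm(star_object, ideal_pupil, brightfield_k, cfg)
        seqs = pf.add_sensor_noise(ds, n_repeats=4, seed=3)
        frames = np.clip(np.stack([pf.average_frames(s) for s in seqs]), 0, None)
        noisy = pf.FPMDataset(frames, ds.k_eff, cfg, {})
        r = pf.epry_reconstruct(noisy, rc=ReconConfig(n_iters=15, upsample=cfg.upsample))
        # non-increasing within a 5% tolerance despite the noise floor
        assert np.all(r.residuals[1:] <= r.residuals[:-1] * 1.05)


class TestReconstructionResidual:
    def test_zero_at_the_simulating_pair(self, star_object, ideal_pupil, star_dataset):
        res = pf.reconstruction_residual(star_dataset, star_object, ideal_pupil)
        assert res < 1e-12

    def test_positive_for_wrong_object(self, star_dataset, star_object, ideal_pupil, cfg):
        uniform = pf.ComplexObject(np.ones_like(star_object.values), star_object.pixel_um)
        assert pf.reconstruction_residual(star_dataset, uniform, ideal_pupil) > 1e-3

    def test_global_phase_gauge_invariance(self, star_dataset, star_object, ideal_pupil):
        rotated = pf.ComplexObject(star_object.values * np.exp(1.3j), star_object.pixel_um)
        a = pf.reconstruction_residual(star_dataset, star_object, ideal_pupil)
        b = pf.reconstruction_residual(star_dataset, rotated, ideal_pupil)
        assert b == pytest.approx(a, abs=1e-12)

    def test_half_pupil_quadratic_form_on_toy_instance(self, cfg):
        # 16^2 toy: with |psi| halved the residual is sum (sqrt(I)/2)^2 / sum I
        # = 1/4; verified against direct enumeration
        n_lo, up = 16, 2
        n_hi = n_lo * up
        rng = np.random.default_rng(5)
        obj = pf.ComplexObject(np.exp(1j * 0.4 * rng.normal(size=(n_hi, n_hi))), cfg.object_pixel_um / up)
        df = 1.0 / (n_lo * cfg.object_pixel_um)
        pup = pf.Pupil.ideal(n_lo, df, cfg.pupil_cutoff)
        ds = pf.forward_fpm(obj, pup, np.zeros((1, 2)), cfg, upsample=up)
        half = pf.Pupil(0.5 * pup.values, pup.cutoff, pup.grid_spacing)
        res = pf.reconstruction_residual(ds, obj, half, upsample=up)
        # direct enumeration oracle
        direct = 0.0
        for frame in ds.frames:
            direct += np.sum((np.sqrt(frame) - 0.5 * np.sqrt(frame)) ** 2)
        direct /= ds.frames.sum()
        assert res == pytest.approx(direct, rel=1e-9)
        assert res == pytest.approx(0.25, rel=1e-9)


class TestRefocusSearch:
    def test_in_focus_estimate_within_one_step(self, star_dataset, cfg):
        dz, _ = pf.refocus_search(
            star_dataset, z_range_um=40.0, coarse_step_um=5.0,
            rc=ReconConfig(n_iters=8, upsample=cfg.upsample),
        )
        assert abs(dz) <= 5.0

    def test_plus_30_um_recovered_and_sharp(self, star_object, ideal_pupil, brightfield_k, cfg):
        """A +30 um axial shift is estimated within +/-5 um and the refocused
        phase image resolves the star below 1.26 um."""
        shifted = ideal_pupil.with_extra_phase(defocus_phase(30.0, cfg, ideal_pupil))
        ds = pf.forward_fpm(star_object, shifted, brightfield_k, cfg)
        dz, result = pf.refocus_search(
            ds, z_range_um=60.0, coarse_step_um=5.0,
            rc=ReconConfig(n_iters=20, upsample=cfg.upsample),
        )
        assert dz == pytest.approx(30.0, abs=5.0)
        px = star_object.pixel_um
        thr = calibrate_star_threshold(cfg, 12, px, star_object.extent_um)
        rep = pf.star_resolution(result.object.phase(), 12, px, contrast_threshold=thr)
        assert rep.resolution_um <= 1.26

    def test_large_negative_shift_over_full_range(self, star_object, ideal_pupil, brightfield_k, cfg):
        shifted = ideal_pupil.with_extra_phase(defocus_phase(-80.0, cfg, ideal_pupil))
        ds = pf.forward_fpm(star_object, shifted, brightfield_k, cfg)
        dz, _ = pf.refocus_search(
            ds, z_range_um=100.0, coarse_step_um=5.0,
            rc=ReconConfig(n_iters=10, upsample=cfg.upsample),
        )
        assert dz == pytest.approx(-80.0, abs=5.0)

    @pytest.mark.parametrize("seed, dz_true", [(0, 22.0), (1, -37.0)])
    def test_dense_scan_oracle_agreement(self, seed, dz_true, ideal_pupil, brightfield_k, cfg):
        """The two-stage argmin agrees with a brute-force dense defocus scan
        within one coarse step on seeded phantoms."""
        n_hi = cfg.tile_px * cfg.upsample
        px = cfg.object_pixel_um / cfg.upsample
        obj = pf.cell_phantom(extent_um=n_hi * px, pixel_um=px, seed=seed)
        shifted = ideal_pupil.with_extra_phase(defocus_phase(dz_true, cfg, ideal_pupil))
        ds = pf.forward_fpm(obj, shifted, brightfield_k, cfg)
        coarse = 5.0
        dz, _ = pf.refocus_search(
            ds, z_range_um=50.0, coarse_step_um=coarse,
            rc=ReconConfig(n_iters=6, upsample=cfg.upsample),
        )
        # dense 2 um scan with the same short object-only reconstructions
        cands = np.arange(-50.0, 50.1, 2.0)
        scores = []
        scan_rc = ReconConfig(n_iters=3, upsample=cfg.upsample, pupil_recovery=False)
        for c in cands:
            trial = ideal_pupil.with_extra_phase(defocus_phase(c, cfg, ideal_pupil))
            r = pf.epry_reconstruct(ds, init_pupil=trial, rc=scan_rc)
            scores.append(pf.reconstruction_residual(ds, r.object, trial, upsample=cfg.upsample))
        dense = float(cands[int(np.argmin(scores))])
        assert abs(dz - dense) <= coarse
        assert dense == pytest.approx(dz_true, abs=2.0)

    def test_range_beyond_150_um_rejected(self, star_dataset, cfg):
        with pytest.raises(GeometryError, match="150"):
            pf.refocus_search(star_dataset, z_range_um=200.0)


class TestAlignObject:
    def test_gauge_removal_recovers_reference(self, band_phantom):
        n = band_phantom.n
        shift = np.exp(2j * np.pi * (3.5 * np.fft.fftfreq(n)[:, None] + 0.0 * np.fft.fftfreq(n)[None, :]))
        moved = np.fft.ifft2(np.fft.fft2(band_phantom.values) * shift) * np.exp(0.9j)
        aligned = pf.align_object(pf.ComplexObject(moved, band_phantom.pixel_um), band_phantom)
        assert np.abs(aligned.values - band_phantom.values).max() < 1e-6
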