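"""Phantoms, the coherent forward model, noise, and whole-plate simulation."""

from __future__ import annotations

import math

import numpy as np
import pytest

import platefpm as pf
from platefpm.geometry import GeometryError
from platefpm.simulate import draw_well_pupil, make_band_pattern, well_id


class TestSiemensStar:
    def test_zero_depth_is_identity(self):
        obj = pf.siemens_star(12, 0.0, 25.6, 0.1)
        assert np.allclose(obj.values, 1.0)

    def test_phase_only(self, star_object):
        assert np.allclose(np.abs(star_object.values), 1.0, atol=1e-12)

    def test_local_period_from_geometry(self):
        # count phase transitions around a circle: 2 N edges per revolution
        obj = pf.siemens_star(40, 1.0, 110.0, 0.1)
        n = obj.n
        c = (n - 1) / 2.0
        r_px = 8.0 / 0.1
        phi = np.linspace(0, 2 * math.pi, 4000, endpoint=False)
        ys = np.clip(np.round(c + r_px * np.sin(phi)).astype(int), 0, n - 1)
        xs = np.clip(np.round(c + r_px * np.cos(phi)).astype(int), 0, n - 1)
        ring = obj.phase()[ys, xs] > 0.5
        edges = np.sum(ring != np.roll(ring, 1))
        assert edges == 2 * 40
        assert 2 * math.pi * 8.0 / 40 == pytest.approx(1.257, abs=1e-3)

    def test_too_coarse_sampling_rejected(self):
        with pytest.raises(GeometryError):
            pf.siemens_star(12, 1.0, 10.0, 0.1)


class TestBeadField:
    def test_seed_reproducibility(self):
        a = pf.bead_field(n_beads=20, extent_um=25.6, pixel_um=0.2, seed=5)
        b = pf.bead_field(n_beads=20, extent_um=25.6, pixel_um=0.2, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_no_beads_is_uniform(self):
        obj = pf.bead_field(n_beads=0, extent_um=25.6, pixel_um=0.2)
        assert np.allclose(obj.values, 1.0)

    def test_mean_phase_linear_in_contrast(self):
        m = []
        for contrast in (0.5, 1.0, 2.0):
            obj = pf.bead_field(n_beads=15, phase_contrast=contrast, extent_um=25.6, pixel_um=0.2, seed=3)
            m.append(obj.phase().mean())
        assert m[1] == pytest.approx(2 * m[0], rel=1e-9)
        assert m[2] == pytest.approx(4 * m[0], rel=1e-9)

    def test_overcrowded_field_raises(self):
        with pytest.raises(GeometryError, match="density"):
            pf.bead_field(n_beads=300, bead_diameter_um=4.0, extent_um=25.6, pixel_um=0.2, max_tries=500)


class TestForwardModel:
    def test_uniform_object_on_axis_is_unit_intensity(self, ideal_pupil, cfg):
        n_hi = cfg.tile_px * cfg.upsample
        obj = pf.ComplexObject(np.ones((n_hi, n_hi)), cfg.object_pixel_um / cfg.upsample)
        ds = pf.forward_fpm(obj, ideal_pupil, np.array([[0.0, 0.0]]), cfg)
        assert np.allclose(ds.frames[0], 1.0, atol=1e-10)

    def test_parseval_energy_conservation(self, star_object, ideal_pupil, brightfield_k, cfg):
        ds = pf.forward_fpm(star_object, ideal_pupil, brightfield_k, cfg)
        j0 = int(np.argmin(np.hypot(brightfield_k[:, 0], brightfield_k[:, 1])))
        n_hi = star_object.n
        n_lo = ideal_pupil.n
        spectrum = np.fft.fftshift(np.fft.fft2(star_object.values)) / (n_hi * n_hi)
        c, h = n_hi // 2, n_lo // 2
        patch = spectrum[c - h : c + h + n_lo % 2, c - h : c + h + n_lo % 2] * ideal_pupil.values
        spectral_energy = np.sum(np.abs(patch) ** 2) * (n_lo * n_lo)
        assert ds.frames[j0].mean() * n_lo * n_lo == pytest.approx(spectral_energy, rel=1e-9)

    def test_darkfield_of_uniform_object_is_empty(self, ideal_pupil, cfg):
        n_hi = cfg.tile_px * cfg.upsample
        obj = pf.ComplexObject(np.ones((n_hi, n_hi)), cfg.object_pixel_um / cfg.upsample)
        lam = cfg.wavelength_um
        k_dark = np.array([[0.30 / lam, 0.0]])  # outside NA 0.23, inside spectrum
        ds = pf.forward_fpm(obj, ideal_pupil, np.r_[[[0.0, 0.0]], k_dark], cfg)
        assert ds.frames[1].sum() < 1e-12 * ds.frames[0].sum()

    def test_k0_equals_coherent_psf_convolution(self, cfg):
        # oracle on a tiny grid: direct circular convolution with the
        # coherent PSF, then decimation (band-limited, hence alias-free)
        n_lo, up = 32, 2
        n_hi = n_lo * up
        px = cfg.object_pixel_um / up
        rng = np.random.default_rng(0)
        obj_v = np.exp(1j * 0.5 * rng.normal(size=(n_hi, n_hi)))
        obj = pf.ComplexObject(obj_v, px)
        df = 1.0 / (n_lo * cfg.object_pixel_um)
        pup = pf.Pupil.ideal(n_lo, df, cfg.pupil_cutoff)
        ds = pf.forward_fpm(obj, pup, np.array([[0.0, 0.0]]), cfg, upsample=up)
        # PSF on the hi-res grid from the embedded pupil
        big = np.zeros((n_hi, n_hi), complex)
        c, h = n_hi // 2, n_lo // 2
        big[c - h : c + h, c - h : c + h] = pup.values
        field_hi = np.fft.ifft2(np.fft.ifftshift(np.fft.fftshift(np.fft.fft2(obj_v)) * big))
        decimated = field_hi[::up, ::up]
        assert ds.frames[0] == pytest.approx(np.abs(decimated) ** 2, rel=1e-9, abs=1e-12)

    def test_out_of_spectrum_k_rejected(self, star_object, ideal_pupil, cfg):
        with pytest.raises(GeometryError, match="spectrum"):
            pf.forward_fpm(star_object, ideal_pupil, np.array([[4.9, 0.0]]), cfg)

    def test_size_mismatch_rejected(self, star_object, cfg):
        bad = pf.Pupil.for_config(cfg.tile_px - 1, cfg)
        with pytest.raises(GeometryError):
            pf.forward_fpm(star_object, bad, np.array([[0.0, 0.0]]), cfg)


class TestSensorNoise:
    @pytest.fixture(scope="class")
    def tiny_ds(self, cfg):
        frames = np.full((3, 64, 64), 0.8)
        return pf.FPMDataset(frames, np.zeros((3, 2)), cfg, {})

    def test_all_zero_amplitudes_identity(self, tiny_ds):
        seqs = pf.add_sensor_noise(tiny_ds, photons_per_unit=None, read_noise_std=0.0, band_pattern_amp=0.0, n_repeats=1)
        assert np.array_equal(seqs[0].repeats[0], tiny_ds.frames[0])

    def test_shot_noise_variance_law(self, cfg):
        frames = np.full((1, 128, 128), 0.5)
        ds = pf.FPMDataset(frames, np.zeros((1, 2)), cfg, {})
        seqs = pf.add_sensor_noise(ds, photons_per_unit=1000.0, read_noise_std=0.0, band_pattern_amp=0.0, n_repeats=1, seed=4)
        var = seqs[0].repeats[0].var()
        assert var == pytest.approx(0.5 / 1000.0, rel=0.05)

    def test_band_pattern_static_across_repeats_and_frames(self, tiny_ds):
        seqs = pf.add_sensor_noise(tiny_ds, photons_per_unit=None, read_noise_std=0.0, band_pattern_amp=0.1, n_repeats=2, seed=9)
        p0 = seqs[0].repeats[0] - tiny_ds.frames[0]
        p1 = seqs[0].repeats[1] - tiny_ds.frames[0]
        p2 = seqs[2].repeats[1] - tiny_ds.frames[2]
        assert np.array_equal(p0, p1) and np.array_equal(p0, p2)
        # horizontal bands: constant along rows
        assert np.allclose(p0, p0[:, :1])

    def test_seeded_bit_reproducibility(self, tiny_ds):
        a = pf.add_sensor_noise(tiny_ds, n_repeats=2, seed=11)
        b = pf.add_sensor_noise(tiny_ds, n_repeats=2, seed=11)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.repeats, sb.repeats)


class TestWellPlateSimulation:
    def test_reduces_to_forward_fpm(self, cfg, brightfield_k):
        layout = pf.WellLayout(n_rows=1, n_cols=1)
        grid = pf.build_led_grid(layout)
        plan = pf.schedule_parallel_illumination(grid, layout, cfg, m=8)
        n_hi = cfg.tile_px * cfg.upsample
        obj = pf.cell_phantom(extent_um=n_hi * cfg.object_pixel_um / cfg.upsample,
                              pixel_um=cfg.object_pixel_um / cfg.upsample, seed=2)
        res = pf.simulate_well_plate(
            {"A1": obj}, plan, grid, layout, cfg,
            aberration_sigmas={}, delta_z_std_um=0.0, seed=0,
        )["A1"]
        ds = res["dataset"]
        # same LED set as the direct brightfield list, same frames
        assert sorted(map(tuple, np.round(ds.k_eff, 9))) == sorted(map(tuple, np.round(brightfield_k, 9)))
        pup = pf.Pupil.for_config(cfg.tile_px, cfg)
        direct = pf.forward_fpm(obj, pup, ds.k_eff, cfg)
        assert np.allclose(ds.frames, direct.frames, atol=1e-12)

    def test_population_sigma_recovered_at_96_draws(self, cfg):
        rng = np.random.default_rng(12)
        sig = pf.simulate.default_aberration_sigmas() if hasattr(pf, "simulate") else {5: 0.88, 6: 0.88, 11: 0.25}
        draws = np.array([
            draw_well_pupil(128, cfg, {5: 0.88, 6: 0.88, 11: 0.25}, rng)[1].coefficients
            for _ in range(96)
        ])
        assert draws[:, 4].std() == pytest.approx(0.88, rel=0.25)
        assert draws[:, 5].std() == pytest.approx(0.88, rel=0.25)
        assert draws[:, 10].std() == pytest.approx(0.25, rel=0.25)

    def test_frame_led_bookkeeping_matches_plan(self, cfg):
        layout = pf.WellLayout(n_rows=2, n_cols=2)
        grid = pf.build_led_grid(layout)
        plan = pf.schedule_parallel_illumination(grid, layout, cfg, m=8)
        n_hi = cfg.tile_px * cfg.upsample
        obj = pf.ComplexObject(np.ones((n_hi, n_hi)), cfg.object_pixel_um / cfg.upsample)
        res = pf.simulate_well_plate(
            {"B2": obj}, plan, grid, layout, cfg,
            aberration_sigmas={}, delta_z_std_um=0.0, seed=1,
        )["B2"]
        wi = [well_id(r, c) for r in range(2) for c in range(2)].index("B2")
        for f, led in zip(res["frame_indices"], res["led_indices"]):
            assert plan.per_well_map[f][wi] == led

    def test_band_pattern_generator_shape(self):
        pat = make_band_pattern((32, 48), 0.2, seed=0)
        assert pat.shape == (32, 48)
        assert np.abs(pat).max() == pytest.approx(0.2)
        assert np.allclose(pat, pat[:, :1])
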