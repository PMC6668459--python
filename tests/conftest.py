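"""Shared fixtures: a scaled-down single-well optical setup.

Most tests run on a 51.2 um tile (128 raw pixels, 512 reconstruction
pixels) with the instrument's real optics (NA 0.23, 533 nm, 3 mm LED pitch
at 33 mm height) and the 21-LED brightfield subset of one well's 7x7
segment; this keeps each reconstruction around a second while exercising
the same physics as the full 110 um production tile.
"""

from __future__ import annotations

import numpy as np
import pytest

import platefpm as pf


@pytest.fixture(scope="session")
def cfg() -> pf.OpticalConfig:
    return pf.OpticalConfig(tile_um=51.2)


@pytest.fixture(scope="session")
def single_well_grid() -> pf.LEDGrid:
    return pf.build_led_grid(pf.WellLayout(n_rows=1, n_cols=1))


@pytest.fixture(scope="session")
def brightfield_k(single_well_grid, cfg) -> np.ndarray:
    """Effective wavevectors of the brightfield LEDs of one well (21 of 49)."""
    lam = cfg.wavelength_um
    ks = [
        pf.illumination_wavevector((x, y), (0.0, 0.0), single_well_grid, cfg)
        for x, y in single_well_grid.positions_mm
    ]
    return np.array([k for k in ks if np.hypot(*k) * lam <= cfg.na_obj])


@pytest.fixture(scope="session")
def star_object(cfg) -> pf.ComplexObject:
    n_hi = cfg.tile_px * cfg.upsample
    px_hi = cfg.object_pixel_um / cfg.upsample
    return pf.siemens_star(n_spoke_pairs=12, phase_depth=1.0, extent_um=n_hi * px_hi, pixel_um=px_hi)


@pytest.fixture(scope="session")
def ideal_pupil(cfg) -> pf.Pupil:
    return pf.Pupil.for_config(cfg.tile_px, cfg)


@pytest.fixture(scope="session")
def star_dataset(star_object, ideal_pupil, brightfield_k, cfg) -> pf.FPMDataset:
    """Noise-free in-focus acquisition of the star under the 21-LED set."""
    return pf.forward_fpm(star_object, ideal_pupil, brightfield_k, cfg)


@pytest.fixture(scope="session")
def band_phantom(cfg) -> pf.ComplexObject:
    """Phase phantom whose spectrum lies inside the synthetic aperture.

    Reconstructions can represent it exactly (no content beyond the
    measured passband and none at the poorly transferred lowest
    frequencies), so recon-vs-truth comparisons isolate algorithmic error.
    """
    n_hi = cfg.tile_px * cfg.upsample
    px_hi = cfg.object_pixel_um / cfg.upsample
    rng = np.random.default_rng(7)
    f = np.fft.fftfreq(n_hi, d=px_hi)
    fx, fy = np.meshgrid(f, f)
    fr = np.hypot(fx, fy)
    band = (fr > 0.04) & (fr < 0.30)
    ph = np.real(np.fft.ifft2(np.fft.fft2(rng.normal(size=(n_hi, n_hi))) * band))
    ph *= 0.8 / ph.std()
    return pf.ComplexObject(np.exp(1j * ph), px_hi)
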