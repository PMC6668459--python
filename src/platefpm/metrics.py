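"""Resolution and image-quality metrics.

Two complementary lateral-resolution read-outs are provided: the Siemens
star metric (azimuthal modulation contrast versus radius, resolution read
as half the local full period at the innermost radius that still carries
threshold contrast) and the full-width-at-half-maximum of a line profile
across a point-like feature. The analytic design formulas
(0.61 lambda / NA lateral, lambda / NA^2 axial, 2 lambda h / w coherent
area width) round out the table used to sanity-check any configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import GeometryError, LEDGrid, OpticalConfig

__all__ = [
    "ResolutionReport",
    "star_resolution",
    "calibrate_star_threshold",
    "fwhm_resolution",
    "theoretical_optics",
]


@dataclass(frozen=True)
class ResolutionReport:
    """Resolution estimate plus the radial contrast profile behind it."""

    resolution_um: float
    method: str
    threshold: float
    at_detection_limit: bool
    radii_um: np.ndarray
    contrast: np.ndarray

    def __post_init__(self) -> None:
        if self.resolution_um <= 0:
            raise ValueError("resolution must be positive")


def _azimuthal_contrast(
    img: np.ndarray,
    center: tuple[float, float],
    radii_px: np.ndarray,
    n_spoke_pairs: int,
    lo: float,
    hi: float,
    harmonics: tuple[int, ...] = (1, 2),
) -> np.ndarray:
    """Spoke-modulation contrast per annulus by harmonic demodulation.

    Each ring is normalized to the robust image range, then demodulated at
    the spoke frequency and its second harmonic (a phase image modulates at
    the spoke frequency; a focused intensity image of a phase star shows
    mostly edge contrast at twice that frequency); the larger of the
    harmonic amplitudes relative to the ring mean is the contrast.
    """
    n_az = 8 * n_spoke_pairs
    phi = np.linspace(0.0, 2.0 * math.pi, n_az, endpoint=False)
    contrast = np.empty(len(radii_px))
    for i, r in enumerate(radii_px):
        ys = center[0] + r * np.sin(phi)
        xs = center[1] + r * np.cos(phi)
        ring = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
        ring = np.clip((ring - lo) / (hi - lo), 0.0, 1.0)
        mean = max(float(ring.mean()), 1e-9)
        amps = [
            2.0 * abs(np.mean(ring * np.exp(1j * h * n_spoke_pairs * phi)))
            for h in harmonics
        ]
        contrast[i] = min(max(amps) / mean, 1.0)
    return contrast


def star_resolution(
    image: np.ndarray,
    n_spoke_pairs: int,
    pixel_um: float,
    center: tuple[float, float] | None = None,
    star_radius_um: float | None = None,
    contrast_threshold: float = 0.2,
) -> ResolutionReport:
    """Read lateral resolution off a Siemens star image.

    The azimuthal spoke-modulation contrast is computed on 1-pixel annuli
    (see :func:`_azimuthal_contrast`); the resolution is half the local
    full period ``2 pi r* / N`` at the smallest radius ``r*`` from which
    the contrast stays at or above ``contrast_threshold`` out to the star's
    edge. When that radius is the innermost measurable annulus the target no
    longer limits the measurement and the report flags the detection limit.
    Use :func:`calibrate_star_threshold` to tie the threshold to the
    analytic coherent-cutoff oracle.
    """
    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    if star_radius_um is None:
        star_radius_um = 0.45 * n * pixel_um
    r_px_max = int(0.95 * star_radius_um / pixel_um)
    # innermost annulus whose local spoke period the pixel grid can carry
    r_px_min = max(3, math.ceil(3.0 * n_spoke_pairs / (2.0 * math.pi)))
    if r_px_max <= r_px_min:
        raise GeometryError("star not detected: too small for the sampling")
    lo, hi = _robust_range(img, center, star_radius_um / pixel_um)
    if hi <= lo:
        raise GeometryError("star not detected: image has no modulation")
    radii = np.arange(r_px_min, r_px_max + 1, dtype=float)
    contrast = _azimuthal_contrast(img, center, radii, n_spoke_pairs, lo, hi)
    # innermost radius from which the contrast stays above threshold outward
    ok = contrast >= contrast_threshold
    if not ok[-1] or not ok.any():
        raise GeometryError("star not detected: no annulus reaches the contrast threshold")
    idx = len(ok) - 1
    while idx > 0 and ok[idx - 1]:
        idx -= 1
    r_star_um = radii[idx] * pixel_um
    full_period = 2.0 * math.pi * r_star_um / n_spoke_pairs
    return ResolutionReport(
        resolution_um=full_period / 2.0,
        method="siemens_star",
        threshold=contrast_threshold,
        at_detection_limit=(idx == 0),
        radii_um=radii * pixel_um,
        contrast=contrast,
    )


def calibrate_star_threshold(
    cfg: OpticalConfig,
    n_spoke_pairs: int,
    pixel_um: float,
    extent_um: float,
    phase_depth: float = 1.0,
) -> float:
    """Contrast threshold tied to the analytic coherent-cutoff oracle.

    Low-passes a synthetic phase star at the objective cutoff ``NA/lambda``
    and returns the contrast measured at the radius whose local half period
    equals the analytic coherent resolution ``lambda / (2 NA)``, so that
    :func:`star_resolution` with this threshold reads the analytic value on
    the oracle image by construction.
    """
    from .simulate import siemens_star  # local import to avoid a cycle

    obj = siemens_star(n_spoke_pairs, phase_depth, extent_um, pixel_um)
    n = obj.n
    f = np.fft.fftfreq(n, d=pixel_um)
    fx, fy = np.meshgrid(f, f)
    keep = fx**2 + fy**2 <= cfg.pupil_cutoff**2
    lp = np.fft.ifft2(np.fft.fft2(obj.values) * keep)
    img = np.angle(lp)
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    lo, hi = _robust_range(img, center, 0.45 * n)
    res_target = cfg.wavelength_um / (2.0 * cfg.na_obj)
    r_target_px = n_spoke_pairs * res_target / math.pi / pixel_um
    c = _azimuthal_contrast(img, center, np.array([r_target_px]), n_spoke_pairs, lo, hi)
    return float(c[0])


def _robust_range(img: np.ndarray, center: tuple[float, float], r_px: float) -> tuple[float, float]:
    y, x = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    disk = (y - center[0]) ** 2 + (x - center[1]) ** 2 <= r_px**2
    vals = img[disk]
    return float(np.percentile(vals, 1)), float(np.percentile(vals, 99))


def fwhm_resolution(profile: np.ndarray, pixel_um: float) -> float:
    """Full width at half maximum (um) of a single-peaked line profile.

    The baseline is the median of the profile's end samples; crossings of
    the half level are located by linear interpolation. A single-pixel
    impulse floors at one pixel width. Invariant to amplitude scaling.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise GeometryError("profile must be a 1-D array of length >= 3")
    n_end = max(1, len(p) // 20)
    baseline = float(np.median(np.concatenate([p[:n_end], p[-n_end:]])))
    peak_idx = int(np.argmax(p))
    peak = p[peak_idx]
    if peak <= baseline:
        raise GeometryError("no peak above the baseline")
    half = baseline + 0.5 * (peak - baseline)

    def cross(idx_range) -> float | None:
        prev = peak_idx
        for i in idx_range:
            if p[i] <= half:
                frac = (p[prev] - half) / (p[prev] - p[i])
                return prev + frac * (i - prev)
            prev = i
        return None

    left = cross(range(peak_idx - 1, -1, -1))
    right = cross(range(peak_idx + 1, len(p)))
    if left is None or right is None:
        raise GeometryError("half-maximum level not crossed on both sides")
    return max(abs(right - left), 1.0) * pixel_um


def theoretical_optics(cfg: OpticalConfig, grid: LEDGrid) -> dict[str, float]:
    """Closed-form design numbers of one mini-microscope channel (um).

    lateral_resolution = 0.61 lambda / NA (incoherent Rayleigh),
    axial_resolution = lambda / NA^2, and coherent_area_width = 2 lambda h / w
    (the lateral scale over which an extended LED of size w at height h
    still illuminates coherently).
    """
    lam = cfg.wavelength_um
    return {
        "lateral_resolution_um": 0.61 * lam / cfg.na_obj,
        "axial_resolution_um": lam / cfg.na_obj**2,
        "coherent_area_width_um": 2.0 * lam * (grid.height_mm * 1000.0) / grid.emitter_size_um,
    }
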