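"""Synthetic-data generation: phantoms, the coherent FPM forward model and
the sensor noise model.

The forward model is the exact adjoint pair of the reconstruction: for each
illumination frame the object spectrum is shifted by the frame's effective
wavevector, cropped to the pupil-supported sub-band, filtered by the complex
pupil, and the squared magnitude of the resulting low-resolution field is
recorded at the sensor sampling. Downsampling happens by spectral cropping,
which keeps the forward/adjoint pair consistent to machine precision.

Phantoms mirror the physical calibration targets of a well-plate
ptychographic imager: phase-only Siemens stars (etched radial gratings),
2 um microbead fields, and smooth cell-like phase blobs. The noise model
adds Poisson shot noise at a configurable photon scale, Gaussian read noise
and a static horizontal band pattern — the signature artefacts of the
consumer-grade CMOS sensors such instruments use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .framestack import FrameSequence
from .geometry import (
    GeometryError,
    IlluminationPlan,
    LEDGrid,
    OpticalConfig,
    WellLayout,
)
from .pupil import Pupil, ZernikeCoeffs, defocus_phase, dilated_support, subpixel_shift_freq, synthesize_phase
from .raytrace import MeniscusModel, trace_illumination

__all__ = [
    "ComplexObject",
    "FPMDataset",
    "siemens_star",
    "bead_field",
    "cell_phantom",
    "forward_fpm",
    "add_sensor_noise",
    "simulate_well_plate",
    "default_aberration_sigmas",
]


@dataclass
class ComplexObject:
    """High-resolution complex transmission map (amplitude * exp(i phase))."""

    values: np.ndarray
    pixel_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.pixel_um <= 0:
            raise GeometryError("object pixel must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def extent_um(self) -> float:
        return self.n * self.pixel_um

    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class FPMDataset:
    """Intensity stack plus per-frame illumination wavevectors.

    The sole input contract of the reconstruction: ``frames`` is
    ``(n_frames, H, W)`` at the raw sensor-referred object sampling, and
    ``k_eff[j]`` is the effective illumination spatial frequency (1/um) of
    frame ``j``.
    """

    frames: np.ndarray
    k_eff: np.ndarray
    cfg: OpticalConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.k_eff = np.asarray(self.k_eff, dtype=float).reshape(-1, 2)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.k_eff.shape[0]:
            raise GeometryError("frames and k_eff must agree on the frame count")
        if self.frames.shape[0] < 1:
            raise GeometryError("need at least one frame")
        if np.any(self.frames < 0):
            raise GeometryError("intensities must be non-negative")
        lam = self.cfg.wavelength_um
        if np.any(np.hypot(self.k_eff[:, 0], self.k_eff[:, 1]) * lam >= 1.0):
            raise GeometryError("|k_eff| * lambda must stay below 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def tile_px(self) -> int:
        return self.frames.shape[-1]


# --------------------------------------------------------------------------
# phantoms


def siemens_star(
    n_spoke_pairs: int = 40,
    phase_depth: float = 1.0,
    extent_um: float = 110.0,
    pixel_um: float = 0.1,
) -> ComplexObject:
    """Phase-only Siemens star: a radial grating whose local full period at
    radius r is ``2 pi r / n_spoke_pairs``.

    Unit amplitude everywhere; the phase alternates between 0 and
    ``phase_depth`` over ``n_spoke_pairs`` azimuthal periods inside a disk of
    diameter ``0.9 * extent``.
    """
    if n_spoke_pairs < 4:
        raise GeometryError("need at least 4 spoke pairs")
    n = int(round(extent_um / pixel_um))
    if n < 128:
        raise GeometryError("extent/pixel must resolve at least 128 samples")
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    r = np.hypot(x - c, y - c) * pixel_um
    theta = np.arctan2(y - c, x - c)
    spokes = np.cos(n_spoke_pairs * theta) >= 0
    disk = r <= 0.45 * extent_um
    phase = np.where(disk & spokes, phase_depth, 0.0)
    return ComplexObject(np.exp(1j * phase), pixel_um)


def bead_field(
    n_beads: int = 40,
    bead_diameter_um: float = 2.0,
    phase_contrast: float = 1.5,
    extent_um: float = 110.0,
    pixel_um: float = 0.1,
    seed: int = 0,
    max_tries: int = 10000,
) -> ComplexObject:
    """Field of non-overlapping spherical phase beads (rejection-sampled).

    Each bead contributes a spherical-chord phase profile peaking at
    ``phase_contrast`` radians. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(extent_um / pixel_um))
    radius = bead_diameter_um / 2.0
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_beads:
        tries += 1
        if tries > max_tries:
            raise GeometryError(
                f"could not place {n_beads} beads after {max_tries} draws; lower the density"
            )
        cx, cy = rng.uniform(radius, extent_um - radius, size=2)
        if all((cx - px) ** 2 + (cy - py) ** 2 >= (2 * radius) ** 2 for px, py in centers):
            centers.append((cx, cy))
    y, x = np.mgrid[0:n, 0:n]
    xu, yu = x * pixel_um, y * pixel_um
    phase = np.zeros((n, n))
    for cx, cy in centers:
        r2 = (xu - cx) ** 2 + (yu - cy) ** 2
        chord = np.sqrt(np.clip(radius**2 - r2, 0.0, None)) / radius
        phase += phase_contrast * chord
    return ComplexObject(np.exp(1j * phase), pixel_um)


def cell_phantom(
    n_cells: int = 12,
    extent_um: float = 110.0,
    pixel_um: float = 0.1,
    phase_scale: float = 1.2,
    seed: int = 0,
) -> ComplexObject:
    """Smooth cell-like phase blobs (anisotropic Gaussians with nuclei)."""
    rng = np.random.default_rng(seed)
    n = int(round(extent_um / pixel_um))
    y, x = np.mgrid[0:n, 0:n]
    xu, yu = x * pixel_um, y * pixel_um
    phase = np.zeros((n, n))
    for _ in range(n_cells):
        cx, cy = rng.uniform(0.1, 0.9, size=2) * extent_um
        sx, sy = rng.uniform(4.0, 9.0, size=2)
        ang = rng.uniform(0, math.pi)
        ca, sa = math.cos(ang), math.sin(ang)
        u = (xu - cx) * ca + (yu - cy) * sa
        v = -(xu - cx) * sa + (yu - cy) * ca
        body = np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
        nucleus = 0.8 * np.exp(-0.5 * ((u / (0.3 * sx)) ** 2 + (v / (0.3 * sy)) ** 2))
        phase += rng.uniform(0.4, 1.0) * (body + nucleus)
    phase *= phase_scale / max(phase.max(), 1e-12)
    return ComplexObject(np.exp(1j * phase), pixel_um)


# --------------------------------------------------------------------------
# forward model


def _shift_px(k: np.ndarray, extent_um: float) -> tuple[int, int]:
    """Quantize a wavevector (1/um) to whole spectral pixels of a tile."""
    return int(round(k[0] * extent_um)), int(round(k[1] * extent_um))


def _split_shift(k: np.ndarray, extent_um: float) -> tuple[int, int, float, float]:
    """Integer spectral-pixel shift plus the sub-pixel remainder of a
    wavevector; the remainder is realised by sampling the pupil at
    ``P(f - delta)`` so arbitrary (off-grid) wavevectors stay exact."""
    sx, sy = _shift_px(k, extent_um)
    return sx, sy, float(k[0] * extent_um - sx), float(k[1] * extent_um - sy)


def forward_fpm(
    obj: ComplexObject,
    pupil: Pupil,
    k_list: np.ndarray,
    cfg: OpticalConfig,
    upsample: int | None = None,
) -> FPMDataset:
    """Simulate the low-resolution intensity stack of an FPM acquisition.

    Per frame j the object spectrum is shifted by ``k_j``, cropped to the
    pupil sub-band, filtered by the pupil and inverse-transformed; the frame
    records the squared magnitude at the sensor sampling (spectral-crop
    downsampling). A uniform object under the on-axis LED yields unit
    intensity everywhere.
    """
    upsample = upsample or cfg.upsample
    if upsample < 2:
        raise GeometryError("upsample must be >= 2")
    n_hi = obj.n
    n_lo = pupil.n
    if n_hi != n_lo * upsample:
        raise GeometryError(
            f"object ({n_hi}) must be pupil ({n_lo}) x upsample ({upsample}) samples wide"
        )
    if not math.isclose(obj.pixel_um * upsample, cfg.object_pixel_um, rel_tol=1e-9):
        raise GeometryError("object pixel inconsistent with cfg.object_pixel / upsample")
    extent = obj.extent_um
    spectrum = np.fft.fftshift(np.fft.fft2(obj.values)) / (n_hi * n_hi)
    c_hi = n_hi // 2
    half = n_lo // 2
    k_arr = np.asarray(k_list, dtype=float).reshape(-1, 2)
    frames = np.empty((len(k_arr), n_lo, n_lo))
    pup_c = pupil.values
    sup_d = dilated_support(n_lo, pupil.grid_spacing, pupil.cutoff)
    for j, k in enumerate(k_arr):
        sx, sy, fx, fy = _split_shift(k, extent)
        r0 = c_hi + sy - half
        c0 = c_hi + sx - half
        if r0 < 0 or c0 < 0 or r0 + n_lo > n_hi or c0 + n_lo > n_hi:
            raise GeometryError(f"k_eff of frame {j} falls outside the simulated spectrum")
        patch = spectrum[r0 : r0 + n_lo, c0 : c0 + n_lo]
        pup_j = subpixel_shift_freq(pup_c, (fy, fx), support=sup_d)
        psi = np.fft.ifft2(np.fft.ifftshift(patch * pup_j)) * (n_lo * n_lo)
        frames[j] = np.abs(psi) ** 2
    return FPMDataset(
        frames=frames,
        k_eff=k_arr,
        cfg=cfg,
        provenance={"upsample": upsample, "source": "forward_fpm"},
    )


# --------------------------------------------------------------------------
# sensor noise


def make_band_pattern(shape: tuple[int, int], amplitude: float, seed: int) -> np.ndarray:
    """Static horizontal-band fixed pattern: smooth random per-row offsets."""
    rng = np.random.default_rng(seed)
    h, w = shape
    rows = rng.normal(size=h)
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    rows = np.convolve(rows, kernel / kernel.sum(), mode="same")
    rows /= max(np.abs(rows).max(), 1e-12)
    return amplitude * np.tile(rows[:, None], (1, w))


def add_sensor_noise(
    ds: FPMDataset,
    photons_per_unit: float | None = 2000.0,
    read_noise_std: float = 5.0,
    band_pattern_amp: float = 0.05,
    n_repeats: int = 1,
    seed: int = 0,
) -> list[FrameSequence]:
    """Corrupt a simulated dataset with shot noise, read noise and a static
    band pattern; returns one repeat stack per illumination frame.

    Shot noise is Poisson at ``photons_per_unit`` photons per unit intensity
    (``None`` disables it); read noise is Gaussian with ``read_noise_std``
    photons; the band pattern is identical across repeats and illuminations.
    Fully determined by ``seed``.
    """
    if n_repeats < 1:
        raise GeometryError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    pattern = make_band_pattern(ds.frames.shape[1:], band_pattern_amp, seed=seed + 1) if band_pattern_amp > 0 else 0.0
    out: list[FrameSequence] = []
    for j in range(ds.n_frames):
        reps = np.empty((n_repeats, *ds.frames.shape[1:]))
        for r in range(n_repeats):
            frame = ds.frames[j]
            if photons_per_unit is not None:
                frame = rng.poisson(frame * photons_per_unit) / photons_per_unit
            if read_noise_std > 0:
                scale = photons_per_unit if photons_per_unit is not None else 1.0
                frame = frame + rng.normal(0.0, read_noise_std / scale, size=frame.shape)
            reps[r] = frame + pattern
        out.append(FrameSequence(repeats=reps, illumination_id=j))
    return out


# --------------------------------------------------------------------------
# whole-plate simulation


def default_aberration_sigmas() -> dict[int, float]:
    """Per-mode standard deviations (radians) of the lens-population
    aberration draw: astigmatism (Noll 5/6) 0.88, primary spherical
    (Noll 11) 0.25."""
    return {5: 0.88, 6: 0.88, 11: 0.25}


def well_id(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1}"


def draw_well_pupil(
    n: int,
    cfg: OpticalConfig,
    sigmas: dict[int, float],
    rng: np.random.Generator,
    delta_z_um: float = 0.0,
) -> tuple[Pupil, ZernikeCoeffs]:
    """One lens drawn from the population statistics, with optional defocus."""
    k_max = max(sigmas) if sigmas else 4
    coef = np.zeros(max(k_max, 4))
    for j, s in sigmas.items():
        coef[j - 1] = rng.normal(0.0, s)
    p = Pupil.for_config(n, cfg)
    phase = np.zeros(p.values.shape)
    if np.any(coef):
        rho, theta = p.rho_theta()
        phase = synthesize_phase(ZernikeCoeffs(coef), rho, theta)
    if delta_z_um != 0.0:
        phase = phase + defocus_phase(delta_z_um, cfg, p)
    if not np.any(phase):
        return p, ZernikeCoeffs(coef)
    return p.with_extra_phase(phase), ZernikeCoeffs(coef)


def simulate_well_plate(
    objects: dict[str, ComplexObject],
    plan: IlluminationPlan,
    grid: LEDGrid,
    layout: WellLayout,
    cfg: OpticalConfig,
    model: MeniscusModel | None = None,
    aberration_sigmas: dict[int, float] | None = None,
    delta_z_std_um: float = 17.0,
    seed: int = 0,
    brightfield_only: bool = True,
) -> dict[str, dict]:
    """Simulate the FPM acquisition of several wells under one shared plan.

    For every requested well (keys of ``objects``, e.g. ``"A8"``) the
    frames assigned to that well by the plan are rendered with
    :func:`forward_fpm`; effective wavevectors go through the meniscus ray
    tracer when a model is given. Each well gets its own pupil drawn from
    the configured Zernike population (defaults: astigmatism sigma 0.88 rad,
    spherical sigma 0.25 rad) and its own defocus offset drawn from the
    well-depth spread (sigma 17 um). Returns per-well dicts with keys
    ``dataset``, ``pupil``, ``zernike``, ``delta_z_um``, ``frame_indices``,
    ``led_indices``.
    """
    if aberration_sigmas is None:
        aberration_sigmas = default_aberration_sigmas()
    rng = np.random.default_rng(seed)
    centers = layout.well_centers_mm()
    ids = [well_id(r, c) for r in range(layout.n_rows) for c in range(layout.n_cols)]
    lam = cfg.wavelength_um
    results: dict[str, dict] = {}
    for wid, obj in objects.items():
        if wid not in ids:
            raise GeometryError(f"unknown well id {wid!r} for this layout")
        wi = ids.index(wid)
        cx, cy = centers[wi]
        dz = float(rng.normal(0.0, delta_z_std_um)) if delta_z_std_um > 0 else 0.0
        n_lo = obj.n // cfg.upsample
        pup, zc = draw_well_pupil(n_lo, cfg, aberration_sigmas, rng, delta_z_um=dz)
        frame_idx: list[int] = []
        led_idx: list[int] = []
        k_eff: list[tuple[float, float]] = []
        for f in plan.in_segment_frames[wi]:
            led = plan.per_well_map[f][wi]
            assert led is not None
            lx, ly = grid.positions_mm[led]
            if model is None:
                from .geometry import illumination_wavevector

                k = illumination_wavevector((lx, ly), (cx, cy), grid, cfg)
            else:
                k = trace_illumination((lx, ly), (cx, cy), grid, model, cfg, well_center_mm=(cx, cy))
            if brightfield_only and math.hypot(*k) * lam > cfg.na_obj + 1e-9:
                continue
            frame_idx.append(f)
            led_idx.append(led)
            k_eff.append(k)
        ds = forward_fpm(obj, pup, np.array(k_eff), cfg)
        ds.provenance.update({"well": wid, "delta_z_um": dz, "seed": seed})
        results[wid] = {
            "dataset": ds,
            "pupil": pup,
            "zernike": zc,
            "delta_z_um": dz,
            "frame_indices": frame_idx,
            "led_indices": led_idx,
        }
    return results
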