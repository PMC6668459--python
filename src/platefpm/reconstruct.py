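"""FPM phase retrieval: embedded pupil recovery (EPRY) with adaptive step
size, the reconstruction residual, and two-stage blind computational
refocusing.

The algorithm stitches the low-resolution intensity frames together in the
spatial-frequency domain. For each frame j the current high-resolution
object spectrum is sampled on the pupil-supported sub-band centred at the
frame's illumination wavevector k_j, giving the modelled low-resolution
field psi_j; its magnitude is replaced by the measured sqrt(I_j), and the
mismatch drives paired gradient updates of the object spectrum O and the
complex pupil P:

    O <- O + alpha * conj(P) * (Psi' - Psi) / max|P|^2
    P <- P + beta  * conj(O_j) * (Psi' - Psi) / max|O_j|^2

The pupil step defaults to the regularized pixel-wise (Gauss-Newton)
variant ``conj(O_j) |O_j| dPsi / (max|O_j| (|O_j|^2 + delta^2))``: object
spectra are DC-dominated, and the plain max-normalized step learns the
pupil only along the DC trajectory of the few brightfield LEDs; the
pixel-wise weighting equalises the learning rate over the disk
(``pupil_update="epry"`` restores the classic step).

One epoch sweeps all frames in ascending |k_j| order. When the epoch
residual fails to improve by at least 1% for ``adapt_patience`` consecutive
epochs the step sizes are multiplied by ``adapt_factor``.

Defocus enters as the angular-spectrum phase kernel folded into the pupil,
so an axial shift of the sample is just one more aberration; blind
refocusing finds it by a linear search over candidate defocus distances
scored with the reconstruction residual (stage 1), then polishes with a
full reconstruction seeded at the best candidate (stage 2).

The recovered object carries the usual phase-retrieval gauge freedoms: a
global phase and a sub-pixel lateral shift. :func:`align_object` removes
both against a reference before any error metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation
from scipy import ndimage

from .geometry import GeometryError
from .pupil import AMPLITUDE_GUARD, Pupil, defocus_phase, dilated_support, subpixel_shift_freq
from .simulate import ComplexObject, FPMDataset, _split_shift

__all__ = [
    "ReconConfig",
    "ReconResult",
    "ReconstructionError",
    "epry_reconstruct",
    "reconstruction_residual",
    "refocus_search",
    "align_object",
]

log = logging.getLogger(__name__)


class ReconstructionError(RuntimeError):
    """Numerical failure (NaN/overflow) during iterative recovery."""


@dataclass(frozen=True)
class ReconConfig:
    """Iteration controls of the EPRY solver."""

    n_iters: int = 30
    step_obj: float = 1.0
    step_pupil: float = 1.0
    adapt_factor: float = 0.5
    adapt_patience: int = 2
    upsample: int = 4
    pupil_recovery: bool = True
    pupil_update: str = "gauss_newton"  # or "epry" (max-normalized)
    gn_delta: float = 1e-4  # relative regularizer of the pixel-wise step
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.adapt_factor < 1.0):
            raise ValueError("adapt_factor must lie in (0, 1)")
        if self.n_iters < 1 or self.upsample < 2:
            raise ValueError("n_iters >= 1 and upsample >= 2 required")
        if self.pupil_update not in ("gauss_newton", "epry"):
            raise ValueError("pupil_update must be 'gauss_newton' or 'epry'")


@dataclass
class ReconResult:
    """Output of one reconstruction: complex object, pupil, residual trace."""

    object: ComplexObject
    pupil: Pupil
    residuals: np.ndarray
    delta_z_hat_um: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if not np.all(np.isfinite(self.residuals)):
            raise ReconstructionError("non-finite residual trace")


def _frame_order(k_eff: np.ndarray) -> np.ndarray:
    """Ascending-|k| (spiral-out) processing order; low NA first aids convergence."""
    return np.argsort(np.hypot(k_eff[:, 0], k_eff[:, 1]), kind="stable")


def _init_object_spectrum(ds: FPMDataset, upsample: int, cutoff: float) -> np.ndarray:
    """Centred high-res spectrum of the upsampled on-axis amplitude, zero phase.

    The spectrum is clipped to the measured synthetic-aperture disk
    (max |k| + pupil cutoff): frequencies outside it are touched by no
    frame, so any initialisation energy there would survive to the output
    as upsampling artefacts.
    """
    j0 = int(np.argmin(np.hypot(ds.k_eff[:, 0], ds.k_eff[:, 1])))
    amp = np.sqrt(np.clip(ds.frames[j0], 0.0, None))
    hi = ndimage.zoom(amp, upsample, order=1, grid_mode=True, mode="grid-wrap")
    n_hi = ds.tile_px * upsample
    S = np.fft.fftshift(np.fft.fft2(hi.astype(complex))) / (n_hi * n_hi)
    df = 1.0 / (n_hi * ds.cfg.object_pixel_um / upsample)
    f = (np.arange(n_hi) - n_hi // 2) * df
    fx, fy = np.meshgrid(f, f)
    k_max = float(np.hypot(ds.k_eff[:, 0], ds.k_eff[:, 1]).max())
    S[fx**2 + fy**2 > (k_max + cutoff + df) ** 2] = 0.0
    return S


def _patch_bounds(k: np.ndarray, extent_um: float, n_hi: int, n_lo: int) -> tuple[int, int, float, float]:
    """Patch corner plus the sub-pixel wavevector remainder (pupil shift)."""
    sx, sy, fx, fy = _split_shift(k, extent_um)
    c_hi, half = n_hi // 2, n_lo // 2
    r0, c0 = c_hi + sy - half, c_hi + sx - half
    if r0 < 0 or c0 < 0 or r0 + n_lo > n_hi or c0 + n_lo > n_hi:
        raise GeometryError("k_eff outside the reconstruction spectrum")
    return r0, c0, fx, fy


def epry_reconstruct(
    ds: FPMDataset,
    init_pupil: Pupil | None = None,
    rc: ReconConfig = ReconConfig(),
    init_spectrum: np.ndarray | None = None,
) -> ReconResult:
    """Iterative FPM reconstruction with embedded pupil recovery.

    On noise-free self-consistent data the residual decreases to numerical
    zero and the simulating (object, pupil) pair is a fixed point. The
    object is initialised from the bilinearly upsampled square root of the
    most axial frame with zero phase unless ``init_spectrum`` is given.
    """
    if ds.n_frames < 9:
        raise GeometryError("EPRY needs at least 9 frames")
    if ds.frames.shape[1] != ds.frames.shape[2]:
        raise GeometryError("frames must be square")
    n_lo = ds.tile_px
    n_hi = n_lo * rc.upsample
    extent = n_hi * (ds.cfg.object_pixel_um / rc.upsample)
    pupil = init_pupil if init_pupil is not None else Pupil.for_config(n_lo, ds.cfg)
    if pupil.n != n_lo:
        raise GeometryError("pupil grid does not match the frame size")
    P = pupil.values.copy()
    support = pupil.support
    S = init_spectrum.copy() if init_spectrum is not None else _init_object_spectrum(ds, rc.upsample, pupil.cutoff)
    if S.shape[0] != n_hi:
        raise GeometryError("init_spectrum size inconsistent with upsample")

    sup_d = dilated_support(n_lo, pupil.grid_spacing, pupil.cutoff)
    order = _frame_order(ds.k_eff)
    sqrt_I = np.sqrt(np.clip(ds.frames, 0.0, None))
    total_I = float(ds.frames.sum())
    alpha, beta = rc.step_obj, rc.step_pupil
    residuals: list[float] = []
    stall = 0
    area = n_lo * n_lo

    for epoch in range(rc.n_iters):
        sq_err = 0.0
        for j in order:
            r0, c0, fx, fy = _patch_bounds(ds.k_eff[j], extent, n_hi, n_lo)
            patch = S[r0 : r0 + n_lo, c0 : c0 + n_lo]
            # off-grid wavevector remainder: use the pupil sampled at P(f - delta)
            P_j = subpixel_shift_freq(P, (fy, fx), support=sup_d)
            Psi = patch * P_j
            psi = np.fft.ifft2(np.fft.ifftshift(Psi)) * area
            mag = np.abs(psi)
            sq_err += float(np.sum((sqrt_I[j] - mag) ** 2))
            psi_p = sqrt_I[j] * psi / np.maximum(mag, 1e-12)
            dPsi = np.fft.fftshift(np.fft.fft2(psi_p - psi)) / area
            if not np.all(np.isfinite(dPsi)):
                raise ReconstructionError(f"non-finite update at epoch {epoch}, frame {int(j)}")
            old_patch = patch.copy()
            patch += alpha * np.conj(P_j) * dPsi / max(float(np.max(np.abs(P_j) ** 2)), 1e-12)
            if rc.pupil_recovery:
                am = np.abs(old_patch)
                mx = max(float(am.max()), 1e-12)
                if rc.pupil_update == "gauss_newton":
                    # regularized pixel-wise step: the object spectrum is
                    # DC-dominated, so a max-normalized step barely moves the
                    # pupil away from the DC trajectory; weighting by
                    # |O|/(|O|^2 + delta^2) equalises the learning rate
                    # across the disk
                    dP = (am * np.conj(old_patch) * dPsi) / (mx * (am**2 + (rc.gn_delta * mx) ** 2))
                else:
                    dP = np.conj(old_patch) * dPsi / (mx * mx)
                P += beta * subpixel_shift_freq(dP, (-fy, -fx), support=sup_d)
                P[~support] = 0.0
                amp = np.abs(P)
                over = amp > AMPLITUDE_GUARD
                if over.any():
                    P[over] *= AMPLITUDE_GUARD / amp[over]
        res = sq_err / total_I
        if residuals and res > residuals[-1] * (1.0 - 0.01):
            stall += 1
            if stall >= rc.adapt_patience:
                alpha *= rc.adapt_factor
                beta *= rc.adapt_factor
                stall = 0
                log.debug("epoch %d: step sizes reduced to (%.3g, %.3g)", epoch, alpha, beta)
        else:
            stall = 0
        residuals.append(res)
        log.info("epoch %d: residual %.3e", epoch, res)

    obj = np.fft.ifft2(np.fft.ifftshift(S)) * (n_hi * n_hi)
    return ReconResult(
        object=ComplexObject(obj, ds.cfg.object_pixel_um / rc.upsample),
        pupil=Pupil(P, pupil.cutoff, pupil.grid_spacing),
        residuals=np.array(residuals),
    )


def reconstruction_residual(ds: FPMDataset, obj: ComplexObject, pupil: Pupil, upsample: int | None = None) -> float:
    """Normalized magnitude-mismatch residual of a candidate (object, pupil).

    ``sum_j sum_px (sqrt(I_j) - |psi_j|)^2 / sum_j sum_px I_j``; exactly zero
    iff the forward model reproduces every frame's magnitude. Invariant to a
    global phase of the object.
    """
    upsample = upsample or ds.cfg.upsample
    n_lo = ds.tile_px
    n_hi = obj.n
    if n_hi != n_lo * upsample:
        raise GeometryError("object size inconsistent with dataset/upsample")
    S = np.fft.fftshift(np.fft.fft2(obj.values)) / (n_hi * n_hi)
    area = n_lo * n_lo
    sup_d = dilated_support(n_lo, pupil.grid_spacing, pupil.cutoff)
    sq = 0.0
    for j in range(ds.n_frames):
        r0, c0, fx, fy = _patch_bounds(ds.k_eff[j], obj.extent_um, n_hi, n_lo)
        pup_j = subpixel_shift_freq(pupil.values, (fy, fx), support=sup_d)
        psi = np.fft.ifft2(np.fft.ifftshift(S[r0 : r0 + n_lo, c0 : c0 + n_lo] * pup_j)) * area
        sq += float(np.sum((np.sqrt(np.clip(ds.frames[j], 0, None)) - np.abs(psi)) ** 2))
    return sq / float(ds.frames.sum())


def refocus_search(
    ds: FPMDataset,
    z_range_um: float = 100.0,
    coarse_step_um: float = 5.0,
    rc: ReconConfig = ReconConfig(),
    init_pupil: Pupil | None = None,
    scan_epochs: int = 3,
) -> tuple[float, "ReconResult"]:
    """Two-stage blind computational refocusing.

    Stage 1 linearly scans defocus candidates over ``[-z_range, +z_range]``
    at ``coarse_step`` spacing; each candidate folds the angular-spectrum
    defocus kernel into an ideal pupil and runs a short object-only
    reconstruction scored by :func:`reconstruction_residual`. Stage 2 runs
    the full EPRY solver seeded with the best candidate's defocus kernel.
    Returns the estimated axial shift and the final result (which also
    carries the stage-1 scan in ``extras['scan']``).
    """
    if z_range_um > 150.0:
        raise GeometryError("refocus range limited to +/-150 um")
    base = init_pupil if init_pupil is not None else Pupil.for_config(ds.tile_px, ds.cfg)
    candidates = np.arange(-z_range_um, z_range_um + coarse_step_um / 2, coarse_step_um)
    scores = np.empty(len(candidates))
    scan_rc = ReconConfig(
        n_iters=scan_epochs,
        step_obj=rc.step_obj,
        adapt_factor=rc.adapt_factor,
        adapt_patience=rc.adapt_patience,
        upsample=rc.upsample,
        pupil_recovery=False,
        seed=rc.seed,
    )
    for i, dz in enumerate(candidates):
        trial = base.with_extra_phase(defocus_phase(dz, ds.cfg, base))
        r = epry_reconstruct(ds, init_pupil=trial, rc=scan_rc)
        scores[i] = reconstruction_residual(ds, r.object, trial, upsample=rc.upsample)
    best = int(np.argmin(scores))
    interior = scores[1:-1]
    prominence = 0.02 * float(scores.max() - scores.min())
    n_minima = int(
        np.sum((interior < scores[:-2] - prominence) & (interior < scores[2:] - prominence))
    )
    if n_minima > 1:
        warnings.warn(
            f"residual-vs-defocus trace has {n_minima} local minima; returning the global argmin",
            RuntimeWarning,
            stacklevel=2,
        )
    dz_hat = float(candidates[best])
    seeded = base.with_extra_phase(defocus_phase(dz_hat, ds.cfg, base))
    final = epry_reconstruct(ds, init_pupil=seeded, rc=rc)
    final.delta_z_hat_um = dz_hat
    final.extras["scan"] = {"delta_z_um": candidates, "residual": scores}
    return dz_hat, final


def align_object(recovered: ComplexObject, reference: ComplexObject) -> ComplexObject:
    """Remove the phase-retrieval gauge (global phase + sub-pixel shift)
    of a recovered object relative to a reference."""
    if recovered.values.shape != reference.values.shape:
        raise GeometryError("objects must share a grid for alignment")
    shift, _, _ = phase_cross_correlation(
        reference.values, recovered.values, upsample_factor=20, normalization=None
    )
    spec = np.fft.fft2(recovered.values)
    fy = np.fft.fftfreq(recovered.n)[:, None]
    fx = np.fft.fftfreq(recovered.n)[None, :]
    shifted = np.fft.ifft2(spec * np.exp(-2j * np.pi * (shift[0] * fy + shift[1] * fx)))
    g = np.vdot(shifted, reference.values)
    phase = g / abs(g) if abs(g) > 0 else 1.0
    return ComplexObject(shifted * phase, recovered.pixel_um)
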