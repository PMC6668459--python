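"""Pupil functions, Zernike wavefront decomposition and defocus kernels.

The complex pupil function of each mini-microscope lives on the
NA-bounded disk in spatial frequency; its phase encodes the lens
aberrations that the embedded-pupil-recovery reconstruction measures in
situ. This module provides the Zernike machinery used to analyse those
pupils (fitting, rotation-invariant mode magnitudes, RMS wavefront
differences) and the angular-spectrum defocus kernel used for
computational refocusing.

Zernike indexing follows the Noll convention throughout: index 1 is
piston, 2/3 tip/tilt, 4 defocus, 5/6 oblique/vertical astigmatism, 11
primary spherical. (Some instrument literature counts defocus as the
"fifth" coefficient by starting the list at 0; this package standardises
on Noll.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase

from .geometry import GeometryError, OpticalConfig

__all__ = [
    "Pupil",
    "ZernikeCoeffs",
    "noll_to_nm",
    "zernike_basis",
    "fit_zernike",
    "synthesize_phase",
    "defocus_phase",
    "rotation_invariant_modes",
    "rms_wavefront_diff",
    "freq_grid",
]

AMPLITUDE_GUARD = 1.5  # divergence guard during pupil recovery


def subpixel_shift_freq(
    values: np.ndarray,
    shift_px: tuple[float, float],
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Shift a centred frequency-domain map by fractional spectral pixels.

    Used to evaluate a pupil at ``P(f - delta)`` when an illumination
    wavevector falls between spectral samples: shifting in frequency is a
    phase ramp in the conjugate domain. The Fourier interpolation leaves
    sinc tails far from the disk, so callers pass a (dilated) ``support``
    mask to keep the shifted pupil compact. Returns the input unchanged for
    a zero shift.
    """
    dy, dx = shift_px
    if dy == 0.0 and dx == 0.0:
        return values
    n = values.shape[0]
    spatial = np.fft.ifft2(np.fft.ifftshift(values))
    u = np.fft.fftfreq(n)
    ramp = np.exp(2j * np.pi * (dy * u[:, None] + dx * u[None, :]))
    out = np.fft.fftshift(np.fft.fft2(spatial * ramp))
    if support is not None:
        out = np.where(support, out, 0.0)
    return out


def dilated_support(n: int, grid_spacing: float, cutoff: float, pad_px: float = 2.0) -> np.ndarray:
    """Pupil support disk grown by ``pad_px`` spectral pixels (for shifted pupils)."""
    fx, fy = freq_grid(n, grid_spacing)
    return fx**2 + fy**2 <= (cutoff + pad_px * grid_spacing) ** 2


def freq_grid(n: int, df: float) -> tuple[np.ndarray, np.ndarray]:
    """Centred spatial-frequency grids (fx, fy) of an n x n map, spacing df (1/um)."""
    f = (np.arange(n) - n // 2) * df
    return np.meshgrid(f, f)


@dataclass
class Pupil:
    """Complex pupil on a centred spatial-frequency grid.

    ``values`` are exactly zero outside the disk ``|f| <= cutoff``;
    amplitude is clipped at a small guard above 1 to keep iterative
    recovery bounded.
    """

    values: np.ndarray
    cutoff: float  # NA / lambda, 1/um
    grid_spacing: float  # 1/um per sample

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        fx, fy = freq_grid(self.values.shape[0], self.grid_spacing)
        self._support = fx**2 + fy**2 <= self.cutoff**2
        self.values = np.where(self._support, self.values, 0.0)
        amp = np.abs(self.values)
        over = amp > AMPLITUDE_GUARD
        if over.any():
            self.values[over] *= AMPLITUDE_GUARD / amp[over]

    @classmethod
    def ideal(cls, n: int, grid_spacing: float, cutoff: float) -> "Pupil":
        """Unaberrated circ-function pupil."""
        fx, fy = freq_grid(n, grid_spacing)
        return cls((fx**2 + fy**2 <= cutoff**2).astype(complex), cutoff, grid_spacing)

    @classmethod
    def for_config(cls, n: int, cfg: OpticalConfig) -> "Pupil":
        """Ideal pupil sampled for an n-pixel tile at the raw sensor sampling."""
        df = 1.0 / (n * cfg.object_pixel_um)
        return cls.ideal(n, df, cfg.pupil_cutoff)

    @property
    def support(self) -> np.ndarray:
        return self._support

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def rho_theta(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-disk polar coordinates of the grid (rho = |f| / cutoff)."""
        fx, fy = freq_grid(self.n, self.grid_spacing)
        return np.hypot(fx, fy) / self.cutoff, np.arctan2(fy, fx)

    def phase(self, unwrap: bool = False) -> np.ndarray:
        """Pupil phase on the support (zero outside); optionally unwrapped."""
        ph = np.angle(self.values)
        if unwrap:
            masked = np.ma.array(ph, mask=~self._support)
            ph = np.asarray(unwrap_phase(masked).filled(0.0))
        return np.where(self._support, ph, 0.0)

    def with_extra_phase(self, extra: np.ndarray) -> "Pupil":
        return Pupil(self.values * np.exp(1j * extra), self.cutoff, self.grid_spacing)


@dataclass(frozen=True)
class ZernikeCoeffs:
    """Zernike coefficients in radians, Noll-indexed from 1."""

    coefficients: np.ndarray  # coefficients[k-1] is Noll mode k

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("Zernike coefficients must be finite")
        object.__setattr__(self, "coefficients", c)

    def __getitem__(self, noll: int) -> float:
        return float(self.coefficients[noll - 1])

    @property
    def n_modes(self) -> int:
        return len(self.coefficients)


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map a Noll index j >= 1 to the radial/azimuthal orders (n, m)."""
    if j < 1:
        raise ValueError(f"invalid Noll index {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    r = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (math.factorial(k) * math.factorial((n + m) // 2 - k) * math.factorial((n - m) // 2 - k))
        )
        r += c * rho ** (n - 2 * k)
    return r


def zernike_basis(indices, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Stack of Noll-normalised Zernike maps on the unit disk.

    Each map has unit RMS over the disk and is zero outside ``rho > 1``.
    Requires the disk to be resolved by at least 32 samples across (use
    :func:`_evaluate_modes` for coarse synthesis grids where fitting
    accuracy is not at stake).
    """
    rho = np.asarray(rho, dtype=float)
    inside = rho <= 1.0
    if inside.sum() < 32 * 32 * math.pi / 4 * 0.5:
        raise GeometryError("grid resolves the unit disk too coarsely (< ~32 samples across)")
    return _evaluate_modes(indices, rho, theta)


def _evaluate_modes(indices, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    inside = rho <= 1.0
    maps = np.zeros((len(list(indices)), *rho.shape))
    for i, j in enumerate(indices):
        n, m = noll_to_nm(j)
        am = abs(m)
        norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
        rad = _radial(n, am, rho)
        if m == 0:
            z = norm * rad
        elif m > 0:
            z = norm * rad * np.cos(am * theta)
        else:
            z = norm * rad * np.sin(am * theta)
        maps[i] = np.where(inside, z, 0.0)
    return maps


def synthesize_phase(coeffs: ZernikeCoeffs, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Phase map (radians) from Zernike coefficients on the unit disk."""
    basis = _evaluate_modes(range(1, coeffs.n_modes + 1), rho, theta)
    return np.tensordot(coeffs.coefficients, basis, axes=1)


def fit_zernike(
    phase_map: np.ndarray,
    rho: np.ndarray,
    theta: np.ndarray,
    k_modes: int = 15,
    unwrap: bool = True,
) -> ZernikeCoeffs:
    """Least-squares Zernike fit of a (possibly wrapped) phase map.

    The map is unwrapped over the disk support first (quality-guided
    unwrapping), then projected onto the first ``k_modes`` Noll modes.
    A noise-free synthesised map round-trips to 1e-6.
    """
    inside = rho <= 1.0
    n_in = int(inside.sum())
    if k_modes > n_in // 4:
        raise ValueError(f"K={k_modes} modes unsupported by {n_in} disk samples")
    ph = np.asarray(phase_map, dtype=float)
    if unwrap:
        masked = np.ma.array(ph, mask=~inside)
        ph = np.asarray(unwrap_phase(masked).filled(0.0))
    basis = zernike_basis(range(1, k_modes + 1), rho, theta)
    a = basis.reshape(k_modes, -1)[:, inside.ravel()].T
    b = ph[inside]
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    return ZernikeCoeffs(coef)


def defocus_phase(delta_z_um: float, cfg: OpticalConfig, rho_or_pupil) -> np.ndarray:
    """Angular-spectrum defocus phase (radians) on the pupil support.

    ``phi(f) = 2 pi dz (sqrt(1/lambda^2 - |f|^2) - 1/lambda)``, anchored so
    the piston at f = 0 vanishes. An axial shift of the sample by ``dz``
    multiplies the pupil by ``exp(i phi)``; refocusing applies the
    conjugate.
    """
    if abs(delta_z_um) > 500.0:
        raise GeometryError("|delta z| beyond the supported 500 um range")
    if isinstance(rho_or_pupil, Pupil):
        fx, fy = freq_grid(rho_or_pupil.n, rho_or_pupil.grid_spacing)
        f2 = fx**2 + fy**2
        support = rho_or_pupil.support
    else:
        f2 = np.asarray(rho_or_pupil, dtype=float) ** 2  # |f| given directly in 1/um
        support = np.ones_like(f2, dtype=bool)
    lam = cfg.wavelength_um
    inv_l2 = 1.0 / lam**2
    kz = np.sqrt(np.clip(inv_l2 - f2, 0.0, None))
    phi = 2.0 * math.pi * delta_z_um * (kz - 1.0 / lam)
    return np.where(support, phi, 0.0)


def rotation_invariant_modes(coeffs: ZernikeCoeffs) -> dict[str, float]:
    """Combine paired azimuthal Zernike modes into rotation-invariant magnitudes.

    Modes with the same (n, |m|) form a sin/cos pair whose quadrature sum
    ``sqrt(a^2 + b^2)`` is invariant under rotation of the pupil;
    rotationally symmetric modes (m = 0) pass through as absolute values.
    Keys are ``"n{n}m{|m|}"`` in ascending order.
    """
    if coeffs.n_modes < 1:
        return {}
    groups: dict[tuple[int, int], float] = {}
    for j in range(1, coeffs.n_modes + 1):
        n, m = noll_to_nm(j)
        key = (n, abs(m))
        groups[key] = groups.get(key, 0.0) + coeffs[j] ** 2
    return {f"n{n}m{m}": math.sqrt(s) for (n, m), s in sorted(groups.items())}


def rms_wavefront_diff(p1: Pupil, p2: Pupil) -> float:
    """RMS (radians) of the piston-removed phase difference of two pupils."""
    if p1.values.shape != p2.values.shape or not math.isclose(p1.grid_spacing, p2.grid_spacing):
        raise GeometryError("pupils must share one frequency grid")
    common = p1.support & p2.support & (np.abs(p1.values) > 0) & (np.abs(p2.values) > 0)
    if not common.any():
        return 0.0
    dphi = np.angle(p1.values[common] * np.conj(p2.values[common]))
    # remove piston as the circular mean so a constant offset cancels exactly
    piston = np.angle(np.mean(np.exp(1j * dphi)))
    resid = np.angle(np.exp(1j * (dphi - piston)))
    return float(np.sqrt(np.mean(resid**2)))
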