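"""Illumination-angle calibration through the liquid column and meniscus.

Cell-culture wells hold a few millimetres of buffer whose free surface forms
a curved meniscus. The liquid refracts every illumination ray, and the
curved surface acts as a concave lens, so the effective source direction at
the sample depends on the lateral field position (the parallax effect).
This module traces LED -> meniscus -> sample rays with Snell's law and
returns the effective in-liquid spatial frequencies that the phase-retrieval
stage must use in place of the free-space wavevectors.

Directions are unit vectors pointing *down* (negative z) from the LED plane
toward the sample at ``z = 0``; the liquid surface sits near
``z = liquid_depth_center``. Only ray directions are computed — no
radiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geometry import GeometryError, LEDGrid, OpticalConfig, illumination_wavevector

__all__ = [
    "MeniscusModel",
    "TotalInternalReflectionError",
    "CalibrationError",
    "refract",
    "trace_illumination",
    "angle_drift_map",
    "spot_tolerance_tilt",
]


class TotalInternalReflectionError(ValueError):
    """The incident ray exceeds the critical angle; no refracted ray exists."""


class CalibrationError(RuntimeError):
    """Ray tracing failed to find the LED -> surface -> sample path."""


@dataclass(frozen=True)
class MeniscusModel:
    """Refractive layer stack inside one well.

    The meniscus is modelled as either a flat liquid surface or a spherical
    cap pinned at the well wall; ``cap_radius_of_curvature_mm < 0`` denotes
    the usual concave-up (centre lower than rim) surface. The plate bottom
    is an optional thin parallel slab handled as a lateral ray offset.
    """

    liquid_index: float = 1.33
    liquid_depth_center_mm: float = 3.0
    plate_bottom_index: float = 1.53  # cyclic olefin copolymer
    plate_bottom_thickness_um: float = 0.0
    well_radius_mm: float = 3.2
    surface_shape: str = "flat"  # "flat" | "spherical_cap"
    cap_radius_of_curvature_mm: float = -10.0

    def __post_init__(self) -> None:
        if self.liquid_index < 1.0 or self.plate_bottom_index < 1.0:
            raise GeometryError("refractive indices must be >= 1")
        if self.liquid_depth_center_mm <= 0:
            raise GeometryError("liquid depth must be positive")
        if self.surface_shape not in ("flat", "spherical_cap"):
            raise GeometryError(f"unknown surface shape {self.surface_shape!r}")
        if self.surface_shape == "spherical_cap" and abs(self.cap_radius_of_curvature_mm) < self.well_radius_mm:
            raise GeometryError("|cap radius of curvature| must be >= well radius")

    # --- surface geometry -------------------------------------------------
    def surface_height_mm(self, x: float, y: float) -> float:
        """z of the liquid surface above the well centre axis at lateral (x, y)."""
        if self.surface_shape == "flat":
            return self.liquid_depth_center_mm
        R = self.cap_radius_of_curvature_mm
        r2 = x * x + y * y
        # spherical cap through (0, 0, depth) with signed curvature radius R:
        # concave-up (R < 0) lifts the surface toward the rim.
        sag = abs(R) - math.sqrt(max(abs(R) ** 2 - r2, 0.0))
        return self.liquid_depth_center_mm + (sag if R < 0 else -sag)

    def surface_normal(self, x: float, y: float) -> np.ndarray:
        """Upward unit normal of the liquid surface at lateral (x, y)."""
        if self.surface_shape == "flat":
            return np.array([0.0, 0.0, 1.0])
        R = self.cap_radius_of_curvature_mm
        rt = math.sqrt(max(abs(R) ** 2 - (x * x + y * y), 1e-30))
        sgn = -1.0 if R < 0 else 1.0
        grad = sgn * np.array([-x / rt, -y / rt])  # d(height)/d(x,y)
        n = np.array([-grad[0], -grad[1], 1.0])
        return n / np.linalg.norm(n)


def refract(direction: np.ndarray, surface_normal: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Refract a unit direction across an interface with Snell's law.

    ``surface_normal`` points against the incoming ray
    (``direction . normal < 0``). Raises on total internal reflection rather
    than clamping.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(surface_normal, dtype=float)
    d = d / np.linalg.norm(d)
    n = n / np.linalg.norm(n)
    cos_i = -float(np.dot(d, n))
    if cos_i < 0:
        n = -n
        cos_i = -cos_i
    eta = n1 / n2
    sin2_t = eta * eta * (1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        raise TotalInternalReflectionError(
            f"sin(theta_t)^2 = {sin2_t:.4f} > 1 for n1={n1}, n2={n2}"
        )
    cos_t = math.sqrt(1.0 - sin2_t)
    t = eta * d + (eta * cos_i - cos_t) * n
    return t / np.linalg.norm(t)


def _trace_to_sample(
    surf_xy: np.ndarray,
    led_mm: np.ndarray,
    model: MeniscusModel,
    well_center_mm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Follow LED -> surface(surf_xy) -> sample plane; return (landing_xy, in-liquid dir)."""
    sx, sy = float(surf_xy[0]), float(surf_xy[1])
    rel = (sx - well_center_mm[0], sy - well_center_mm[1])
    sz = model.surface_height_mm(*rel)
    p_surf = np.array([sx, sy, sz])
    d_in = p_surf - led_mm
    d_in = d_in / np.linalg.norm(d_in)
    normal = model.surface_normal(*rel)
    d_liq = refract(d_in, normal, 1.0, model.liquid_index)
    if d_liq[2] >= 0:
        raise CalibrationError("refracted ray does not travel toward the sample")
    # straight run through the liquid down to z = 0
    t = sz / (-d_liq[2])
    landing = p_surf[:2] + t * d_liq[:2]
    if model.plate_bottom_thickness_um > 0:
        # thin parallel slab below the liquid: pure lateral offset, direction
        # restored on exit
        t_mm = model.plate_bottom_thickness_um / 1000.0
        d_slab = refract(d_liq, np.array([0.0, 0.0, 1.0]), model.liquid_index, model.plate_bottom_index)
        landing = landing + t_mm * (d_slab[:2] / (-d_slab[2]) - d_liq[:2] / (-d_liq[2]))
    return landing, d_liq


def trace_illumination(
    led_xy_mm: tuple[float, float],
    field_point_mm: tuple[float, float],
    grid: LEDGrid,
    model: MeniscusModel,
    cfg: OpticalConfig,
    well_center_mm: tuple[float, float] = (0.0, 0.0),
    tol_mm: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Effective illumination spatial frequency (1/um) at a field point.

    Solves for the meniscus-surface point through which the LED ray reaches
    the field point, then returns ``n_liquid * (dir_x, dir_y) / lambda`` of
    the in-liquid ray — the grating shift the reconstruction must apply.
    With all indices set to 1 this reduces exactly to the free-space
    :func:`platefpm.geometry.illumination_wavevector`.
    """
    led = np.array([led_xy_mm[0], led_xy_mm[1], grid.height_mm])
    target = np.asarray(field_point_mm, dtype=float)
    wc = np.asarray(well_center_mm, dtype=float)

    def residual(surf_xy: np.ndarray) -> np.ndarray:
        landing, _ = _trace_to_sample(surf_xy, led, model, wc)
        return landing - target

    # initial guess: straight-line intersection with the nominal surface plane
    z0 = model.liquid_depth_center_mm
    frac = (grid.height_mm - z0) / grid.height_mm
    guess = led[:2] + frac * (target - led[:2])
    def solve_from(start: np.ndarray) -> tuple[np.ndarray, float]:
        # solve in offset coordinates: MINPACK's finite-difference step is
        # relative to |x| and degenerates when a coordinate is ~0 mm
        sol = optimize.root(
            lambda d: residual(start + d), np.zeros(2), method="hybr",
            tol=tol_mm * 1e-3, options={"maxfev": max_iter * 4, "eps": 1e-6},
        )
        x = start + sol.x
        return x, float(np.linalg.norm(residual(x)))

    best, err = solve_from(guess)
    if err > tol_mm:
        # a strongly curved cap folds the surface-point -> landing-point map
        # (caustics); restart from the best candidate of a coarse grid scan
        r_scan = max(model.well_radius_mm, 1.0)
        offs = np.linspace(-r_scan, r_scan, 21)
        cands = [guess + np.array([dx, dy]) for dx in offs for dy in offs]
        norms = []
        for c in cands:
            try:
                norms.append(float(np.linalg.norm(residual(c))))
            except (TotalInternalReflectionError, CalibrationError):
                norms.append(np.inf)
        start = cands[int(np.argmin(norms))]
        trials = [(start, float(np.min(norms))), solve_from(start)]
        try:
            lsq = optimize.least_squares(residual, start, xtol=tol_mm * 1e-3, max_nfev=max_iter * 10)
            trials.append((lsq.x, float(np.linalg.norm(residual(lsq.x)))))
        except (TotalInternalReflectionError, CalibrationError):
            pass
        for cand, cand_err in trials:
            if cand_err < err:
                best, err = cand, cand_err
    if err > tol_mm:
        raise CalibrationError(
            f"surface-intersection search did not converge: residual {err:.3e} mm"
        )
    _, d_liq = _trace_to_sample(best, led, model, wc)
    lam = cfg.wavelength_um
    n = model.liquid_index
    return (n * float(d_liq[0]) / lam, n * float(d_liq[1]) / lam)


def angle_drift_map(
    led_xy_mm: tuple[float, float],
    field_points_mm: np.ndarray,
    model: MeniscusModel,
    grid: LEDGrid,
    cfg: OpticalConfig,
    well_center_mm: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Incidence angle (degrees, in-liquid from vertical) per field point.

    The spread ``max - min`` quantifies the parallax drift across the field
    of view; a curved meniscus amplifies it well beyond the purely geometric
    value.
    """
    pts = np.atleast_2d(np.asarray(field_points_mm, dtype=float))
    if pts.shape[0] < 1:
        raise GeometryError("at least one field point required")
    angles = np.empty(pts.shape[0])
    lam = cfg.wavelength_um
    for i, p in enumerate(pts):
        fx, fy = trace_illumination(led_xy_mm, (p[0], p[1]), grid, model, cfg, well_center_mm)
        sin_t = math.hypot(fx, fy) * lam / model.liquid_index
        angles[i] = math.degrees(math.asin(min(sin_t, 1.0)))
    return angles


def spot_tolerance_tilt(delta_mm: float, span_wells: int, well_pitch_mm: float) -> float:
    """Plate-tilt tolerance (degrees) from an allowed axial spot excursion.

    A spot-size budget of ``delta`` over a lever arm of ``span_wells`` well
    pitches allows a relative tilt of ``atan(delta / (pitch * span))`` — about
    1 degree for 2 mm over 11 pitches of 9 mm.
    """
    if delta_mm < 0 or span_wells <= 0 or well_pitch_mm <= 0:
        raise GeometryError("inputs must be positive")
    return math.degrees(math.atan2(delta_mm, well_pitch_mm * span_wells))
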