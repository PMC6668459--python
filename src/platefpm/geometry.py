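"""Illumination geometry for array-level Fourier ptychographic imaging.

A multi-well plate sits under a large planar LED matrix. Every well is
served by its own miniature microscope, and all mini-microscopes share the
single LED array: each well "sees" a square segment of the array centred on
the well, and neighbouring wells reuse most of each other's segments.
This module builds the shared LED lattice, computes free-space illumination
wavevectors (the liquid-corrected version lives in :mod:`platefpm.raytrace`),
and schedules the parallel illumination patterns that light every well while
keeping at most one source inside each objective's acceptance cone.

Conventions
-----------
Right-handed coordinates with the origin at the plate centre, ``x`` along
the long (12-well) plate axis, the sample plane at ``z = 0`` and the LED
plane at ``z = +h``. Lateral geometry is expressed in millimetres at this
surface; spatial frequencies are returned in 1/um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WellLayout",
    "LEDGrid",
    "IlluminationPlan",
    "OpticalConfig",
    "GeometryError",
    "build_led_grid",
    "segment_reuse_fraction",
    "illumination_wavevector",
    "acceptance_radius",
    "schedule_parallel_illumination",
]

MM_TO_UM = 1000.0


class GeometryError(ValueError):
    """Raised for invalid or inconsistent optical geometry."""


@dataclass(frozen=True)
class WellLayout:
    """Rectangular lattice of wells (default: standard 96-well plate)."""

    n_rows: int = 8
    n_cols: int = 12
    well_pitch_mm: float = 9.0
    well_radius_mm: float = 3.2

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("well counts must be positive")
        if self.well_pitch_mm <= 0:
            raise GeometryError("well_pitch_mm must be positive")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_centers_mm(self) -> np.ndarray:
        """(n_wells, 2) array of well-centre (x, y), row-major.

        Centres sit on integer multiples of the well pitch (the central
        well defines the origin), so they stay on the LED lattice whose
        pitch divides the well pitch.
        """
        xs = (np.arange(self.n_cols) - self.n_cols // 2) * self.well_pitch_mm
        ys = (np.arange(self.n_rows) - self.n_rows // 2) * self.well_pitch_mm
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class LEDGrid:
    """Planar LED lattice at height ``h`` above the sample plane.

    ``positions_mm`` holds unique lateral (x, y) coordinates; every
    coordinate is an integer multiple of ``led_pitch_mm`` relative to the
    grid origin.
    """

    positions_mm: np.ndarray
    height_mm: float = 33.0
    led_pitch_mm: float = 3.0
    emitter_size_um: float = 250.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "positions_mm", pos)
        if self.height_mm <= 0:
            raise GeometryError("LED height must be positive")
        if self.led_pitch_mm <= 0:
            raise GeometryError("led_pitch_mm must be positive")
        steps = pos / self.led_pitch_mm
        if not np.allclose(steps, np.round(steps), atol=1e-9):
            raise GeometryError("LED positions must sit on the pitch lattice")
        if len({(round(p[0] / self.led_pitch_mm), round(p[1] / self.led_pitch_mm)) for p in pos}) != len(pos):
            raise GeometryError("LED positions must be unique")

    @property
    def n_leds(self) -> int:
        return len(self.positions_mm)


@dataclass(frozen=True)
class OpticalConfig:
    """Fixed optical constants of one mini-microscope channel."""

    wavelength_nm: float = 533.0
    na_obj: float = 0.23
    magnification: float = 4.0
    object_pixel_um: float = 0.4
    fov_mm: tuple[float, float] = (1.1, 0.85)
    object_to_sensor_mm: float = 48.0
    working_distance_mm: float = 4.0
    segment_width_mm: float = 18.0
    tile_um: float = 110.0
    upsample: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.na_obj < 1.0):
            raise GeometryError("na_obj must lie in (0, 1)")
        if min(self.fov_mm) <= 0:
            raise GeometryError("fov must be positive")
        # Nyquist guard for the reconstruction (object-side) sampling
        if self.object_pixel_um > self.wavelength_um / (4.0 * self.na_obj * self.upsample) * self.upsample * 2:
            raise GeometryError("object pixel too coarse for the optical cutoff")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / 1000.0

    @property
    def pupil_cutoff(self) -> float:
        """Coherent pupil cutoff NA/lambda, in 1/um."""
        return self.na_obj / self.wavelength_um

    @property
    def tile_px(self) -> int:
        """Raw (sensor-sampled) pixels across one reconstruction tile."""
        return int(round(self.tile_um / self.object_pixel_um))


@dataclass(frozen=True)
class IlluminationPlan:
    """Parallel illumination schedule.

    ``patterns`` is an ordered list of LED index sets lit simultaneously in
    one frame; ``per_well_map[frame][well]`` gives the single LED index
    assigned to that well in that frame, or ``None`` when no source falls in
    the well's segment.
    """

    patterns: list[frozenset[int]]
    per_well_map: list[list[int | None]]
    source_separation_m: int
    in_segment_frames: list[list[int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.patterns)


def build_led_grid(
    layout: WellLayout,
    led_pitch_mm: float = 3.0,
    segment_width_mm: float = 18.0,
    height_mm: float = 33.0,
    emitter_size_um: float = 250.0,
) -> LEDGrid:
    """Union of the per-well LED segments over all wells, deduplicated.

    Each well uses a ``segment_width`` x ``segment_width`` square segment of
    the lattice centred on the well; adjacent wells share most of it. The
    returned count obeys the closed form
    ``((n_cols-1)*pitch + segment)/led_pitch + 1`` per axis.
    """
    if segment_width_mm < layout.well_pitch_mm:
        raise GeometryError(
            f"segment width {segment_width_mm} mm smaller than well pitch "
            f"{layout.well_pitch_mm} mm"
        )
    for name, length in (("segment_width", segment_width_mm), ("well_pitch", layout.well_pitch_mm)):
        ratio = length / led_pitch_mm
        if abs(ratio - round(ratio)) > 1e-9:
            raise GeometryError(
                f"led_pitch {led_pitch_mm} mm does not divide {name} {length} mm"
            )
    half = segment_width_mm / 2.0
    n_seg = int(round(segment_width_mm / led_pitch_mm)) + 1
    offsets = np.linspace(-half, half, n_seg)
    centers = layout.well_centers_mm()
    seen: set[tuple[int, int]] = set()
    for cx, cy in centers:
        for ox in offsets:
            for oy in offsets:
                seen.add((round((cx + ox) / led_pitch_mm), round((cy + oy) / led_pitch_mm)))
    pos = np.array(sorted(seen)) * led_pitch_mm
    return LEDGrid(
        positions_mm=pos,
        height_mm=height_mm,
        led_pitch_mm=led_pitch_mm,
        emitter_size_um=emitter_size_um,
    )


def segment_reuse_fraction(well_pitch_mm: float, segment_width_mm: float) -> float:
    """Fraction of a well's LED segment area shared with adjacent wells.

    With mini-microscopes packed at pitch ``p`` under segments of width
    ``s >= p``, only the central ``p x p`` patch of each segment is
    exclusive; the reused fraction is ``1 - (p/s)**2`` (0.75 for the
    default 9 mm pitch under 18 mm segments).
    """
    if well_pitch_mm <= 0:
        raise GeometryError("well pitch must be positive")
    if segment_width_mm < well_pitch_mm:
        raise GeometryError("segment narrower than the well pitch: invalid geometry")
    return 1.0 - (well_pitch_mm / segment_width_mm) ** 2


def illumination_wavevector(
    led_xy_mm: tuple[float, float],
    field_point_mm: tuple[float, float],
    grid: LEDGrid,
    cfg: OpticalConfig,
) -> tuple[float, float]:
    """Free-space illumination spatial frequency (fx, fy) in 1/um.

    Direction cosines of the LED -> field-point ray divided by the vacuum
    wavelength; no liquid. Satisfies ``|f| * lambda < 1`` strictly.
    """
    h = grid.height_mm
    if h <= 0:
        raise GeometryError("field point must lie below the LED plane")
    dx = field_point_mm[0] - led_xy_mm[0]
    dy = field_point_mm[1] - led_xy_mm[1]
    norm = math.sqrt(dx * dx + dy * dy + h * h)
    lam = cfg.wavelength_um
    return (dx / norm / lam, dy / norm / lam)


def acceptance_radius(grid: LEDGrid, cfg: OpticalConfig, na_illum_max: float | None = None) -> float:
    """LED-plane radius (mm) of the illumination cone over a well centre.

    An LED inside this disk illuminates the well at NA below
    ``na_illum_max`` (default: the objective NA, i.e. the brightfield cone).
    """
    if na_illum_max is None:
        na_illum_max = cfg.na_obj
    if not (0.0 < na_illum_max < 1.0):
        raise GeometryError("na_illum_max must lie in (0, 1)")
    return grid.height_mm * math.tan(math.asin(na_illum_max))


def schedule_parallel_illumination(
    grid: LEDGrid,
    layout: WellLayout,
    cfg: OpticalConfig,
    m: int = 8,
    na_illum_max: float | None = None,
) -> IlluminationPlan:
    """Schedule m^2 lattice-shifted patterns lighting all wells in parallel.

    Every frame lights a rectangular sub-lattice of the LED array with
    source-to-source separation ``m`` LED pitches; the shift sweeps all
    ``m**2`` offset classes so the union over frames covers every LED. The
    separation must exceed the acceptance-cone diameter so that no well ever
    sees two sources at once (validated up front and re-verified
    exhaustively).

    ``per_well_map`` assigns, per frame, the unique lit LED inside each
    well's segment; ``in_segment_frames[well]`` lists the frames useful for
    that well's reconstruction.
    """
    r_acc = acceptance_radius(grid, cfg, na_illum_max)
    sep_mm = m * grid.led_pitch_mm
    if sep_mm <= 2.0 * r_acc:
        raise GeometryError(
            f"m={m} gives source separation {sep_mm} mm <= acceptance cone "
            f"diameter {2 * r_acc:.2f} mm: two LEDs could light one well"
        )
    pos = grid.positions_mm
    pitch = grid.led_pitch_mm
    ij = np.round(pos / pitch).astype(int)  # lattice indices of each LED
    centers = layout.well_centers_mm()
    half_seg = cfg.segment_width_mm / 2.0

    patterns: list[frozenset[int]] = []
    per_well_map: list[list[int | None]] = []
    in_segment: list[list[int]] = [[] for _ in range(len(centers))]
    covered: list[set[int]] = [set() for _ in range(len(centers))]

    for si in range(m):
        for sj in range(m):
            mask = (np.mod(ij[:, 0] - si, m) == 0) & (np.mod(ij[:, 1] - sj, m) == 0)
            lit = np.nonzero(mask)[0]
            frame = len(patterns)
            patterns.append(frozenset(int(k) for k in lit))
            row: list[int | None] = []
            for wi, (cx, cy) in enumerate(centers):
                d = pos[lit] - (cx, cy)
                inside = lit[(np.abs(d[:, 0]) <= half_seg + 1e-9) & (np.abs(d[:, 1]) <= half_seg + 1e-9)]
                # also re-verify the acceptance-cone constraint exhaustively
                in_cone = lit[np.hypot(pos[lit, 0] - cx, pos[lit, 1] - cy) <= r_acc + 1e-9]
                if len(in_cone) > 1:
                    raise GeometryError(
                        f"constraint violation: frame {frame}, well {wi}, "
                        f"LEDs {int(in_cone[0])} and {int(in_cone[1])} both in cone"
                    )
                if len(inside) == 0:
                    row.append(None)
                else:
                    # segment wider than the source separation would admit
                    # several in-segment LEDs; keep the one nearest the well
                    # axis (unique by construction when m*pitch >= segment)
                    k = int(inside[np.argmin(np.hypot(pos[inside, 0] - cx, pos[inside, 1] - cy))])
                    row.append(k)
                    covered[wi].add(k)
                    in_segment[wi].append(frame)
            per_well_map.append(row)

    # coverage: the union of assignments must visit the whole per-well segment.
    # When m*pitch equals the segment width the two segment-edge LEDs share an
    # offset class and appear in the same frame, so only interior coverage can
    # be demanded; for m*pitch > segment width the full segment is enforced.
    strict = sep_mm > cfg.segment_width_mm + 1e-9
    tol = 1e-9 if strict else -1e-6
    for wi, (cx, cy) in enumerate(centers):
        d = pos - (cx, cy)
        seg = set(
            np.nonzero(
                (np.abs(d[:, 0]) < half_seg + tol) & (np.abs(d[:, 1]) < half_seg + tol)
            )[0].tolist()
        )
        if not seg <= covered[wi]:
            missing = sorted(seg - covered[wi])
            raise GeometryError(f"plan does not cover segment of well {wi}: missing LEDs {missing[:5]}")

    return IlluminationPlan(
        patterns=patterns,
        per_well_map=per_well_map,
        source_separation_m=m,
        in_segment_frames=in_segment,
    )
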