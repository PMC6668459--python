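"""Tile partitioning of the per-well field of view and feather-blend
stitching of complex reconstructions.

The full 1.1 mm x 0.85 mm field is reconstructed as a grid of ~110 um
tiles (8 x 10 for the default geometry) that overlap slightly so the
per-tile results can be blended into a seamless mosaic. Because each tile's
phase retrieval carries an independent global phase, the tiles are first
gauge-aligned on their overlaps, then combined as complex values with
distance-to-edge (feather) weights; blending the complex field rather than
the wrapped phase avoids 2-pi seam artefacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError

__all__ = ["TileGrid", "partition_fov", "feather_blend", "align_tile_gauge", "save_stitched"]


@dataclass(frozen=True)
class TileGrid:
    """Row-major list of half-open pixel boxes (r0, r1, c0, c1) covering a FOV."""

    boxes: tuple[tuple[int, int, int, int], ...]
    shape: tuple[int, int]  # full-FOV pixels (rows, cols)
    n_rows: int
    n_cols: int
    overlap_fraction: float

    @property
    def n_tiles(self) -> int:
        return len(self.boxes)


def partition_fov(
    fov_um: tuple[float, float],
    tile_um: float = 110.0,
    overlap: float = 0.05,
    pixel_um: float = 0.4,
) -> TileGrid:
    """Partition a FOV into the minimal grid of nominal ``tile_um`` tiles.

    The FOV (width x height, um) is split into ``ceil(extent / tile)``
    segments per axis; each tile box is the segment grown by half the
    overlap margin on every side (clipped at the FOV border), so interior
    neighbours share at least ``overlap`` of a tile width. The default
    geometry (1.1 mm x 0.85 mm, 110 um tiles) gives 10 x 8 = 80 tiles.
    """
    if not (0.0 <= overlap < 0.5):
        raise GeometryError("overlap fraction must lie in [0, 0.5)")
    w_px = int(round(fov_um[0] / pixel_um))
    h_px = int(round(fov_um[1] / pixel_um))
    t_px = int(round(tile_um / pixel_um))
    if t_px > min(w_px, h_px):
        raise GeometryError("tile larger than the FOV")
    n_cols = math.ceil(w_px / t_px)
    n_rows = math.ceil(h_px / t_px)
    margin = math.ceil(t_px * overlap / 2)
    col_edges = np.round(np.linspace(0, w_px, n_cols + 1)).astype(int)
    row_edges = np.round(np.linspace(0, h_px, n_rows + 1)).astype(int)
    boxes = []
    for r in range(n_rows):
        for c in range(n_cols):
            r0 = max(row_edges[r] - margin, 0)
            r1 = min(row_edges[r + 1] + margin, h_px)
            c0 = max(col_edges[c] - margin, 0)
            c1 = min(col_edges[c + 1] + margin, w_px)
            boxes.append((int(r0), int(r1), int(c0), int(c1)))
    return TileGrid(
        boxes=tuple(boxes),
        shape=(h_px, w_px),
        n_rows=n_rows,
        n_cols=n_cols,
        overlap_fraction=overlap,
    )


def _feather_weight(h: int, w: int) -> np.ndarray:
    """Separable distance-to-edge ramp, strictly positive, peaking centrally."""
    ry = np.minimum(np.arange(h) + 1, h - np.arange(h))
    rx = np.minimum(np.arange(w) + 1, w - np.arange(w))
    return ry[:, None].astype(float) * rx[None, :]


def feather_blend(tiles: list[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Blend per-tile complex images into the full FOV with feather weights.

    Per pixel the output is the weight-normalized sum of the contributing
    tiles' complex values, with weights proportional to the distance to each
    tile's edge; weights sum to one everywhere, so a constant input is
    passed through exactly and single-tile regions are untouched.
    """
    if len(tiles) != grid.n_tiles:
        missing = list(range(len(tiles), grid.n_tiles))
        raise GeometryError(f"missing tiles for boxes {missing}")
    acc = np.zeros(grid.shape, dtype=complex)
    wsum = np.zeros(grid.shape)
    for img, (r0, r1, c0, c1) in zip(tiles, grid.boxes):
        if img.shape != (r1 - r0, c1 - c0):
            raise GeometryError(
                f"tile shape {img.shape} does not match box {(r0, r1, c0, c1)}"
            )
        w = _feather_weight(r1 - r0, c1 - c0)
        acc[r0:r1, c0:c1] += w * img
        wsum[r0:r1, c0:c1] += w
    if np.any(wsum == 0):
        raise GeometryError("tile grid does not cover the FOV")
    return acc / wsum


def align_tile_gauge(tiles: list[np.ndarray], grid: TileGrid) -> list[np.ndarray]:
    """Remove per-tile global phases using the overlap regions.

    Each per-tile phase retrieval is defined only up to a unit-modulus
    constant; tiles are visited row-major, and each is rotated by the phase
    that best matches the already-anchored canvas on its overlap (the first
    tile anchors the gauge). Zero-energy overlaps fall back to the identity
    gauge with a warning.
    """
    if len(tiles) != grid.n_tiles:
        raise GeometryError("one image per tile required")
    canvas = np.zeros(grid.shape, dtype=complex)
    have = np.zeros(grid.shape, dtype=bool)
    out: list[np.ndarray] = []
    for i, (img, (r0, r1, c0, c1)) in enumerate(zip(tiles, grid.boxes)):
        img = np.asarray(img, dtype=complex)
        if i > 0:
            ov = have[r0:r1, c0:c1]
            g = np.sum(canvas[r0:r1, c0:c1][ov] * np.conj(img[ov]))
            if abs(g) > 0:
                img = img * (g / abs(g))
            else:
                warnings.warn(
                    f"tile {i}: zero-energy overlap, identity gauge", RuntimeWarning, stacklevel=2
                )
        out.append(img)
        fresh = ~have[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1][fresh] = img[fresh]
        have[r0:r1, c0:c1] = True
    return out


def save_stitched(prefix, mosaic: np.ndarray, grid: TileGrid) -> None:
    """Write a stitched complex mosaic to disk.

    Produces ``<prefix>_amplitude.tif`` and ``<prefix>_phase.tif`` (float32),
    an 8-bit ``<prefix>_preview.png`` of the phase, and ``<prefix>_grid.json``
    with the tile-grid metadata.
    """
    import json
    from pathlib import Path

    import tifffile
    from PIL import Image

    prefix = Path(prefix)
    amp = np.abs(mosaic).astype(np.float32)
    phase = np.angle(mosaic).astype(np.float32)
    tifffile.imwrite(f"{prefix}_amplitude.tif", amp)
    tifffile.imwrite(f"{prefix}_phase.tif", phase)
    lo, hi = np.percentile(phase, [1, 99])
    preview = np.clip((phase - lo) / max(hi - lo, 1e-12), 0, 1)
    Image.fromarray((255 * preview).astype(np.uint8)).save(f"{prefix}_preview.png")
    meta = {
        "shape": list(grid.shape),
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "overlap_fraction": grid.overlap_fraction,
        "boxes": [list(b) for b in grid.boxes],
    }
    Path(f"{prefix}_grid.json").write_text(json.dumps(meta))
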