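"""Digital frame averaging and fixed-pattern removal.

Consumer-grade CMOS sensors trade dynamic range for cost; the remedy here
is purely computational: average repeated video frames of the same
field-of-view to beat down temporal noise (std shrinks as 1/sqrt(n) on
white noise), then estimate and subtract the static band-like fixed
pattern, which is the only image component that stays constant across
different illumination angles. A sharpest-plane selector handles the
mechanically z-scanned fluorescence-like channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSequence",
    "average_frames",
    "remove_static_pattern",
    "select_sharpest_plane",
]


@dataclass
class FrameSequence:
    """Repeated frames acquired under one identical illumination."""

    repeats: np.ndarray  # (n_repeats, H, W)
    illumination_id: int | None = None
    z_um: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.repeats = np.atleast_3d(np.asarray(self.repeats, dtype=float))
        if self.repeats.ndim != 3 or self.repeats.shape[0] < 1:
            raise ValueError("repeats must be a non-empty (n, H, W) stack")

    @property
    def n_repeats(self) -> int:
        return self.repeats.shape[0]


def average_frames(seq: FrameSequence) -> np.ndarray:
    """Per-pixel mean over the repeats of one illumination."""
    if seq.n_repeats < 1:
        raise ValueError("empty frame sequence")
    return seq.repeats.mean(axis=0)


def remove_static_pattern(
    seqs: list[FrameSequence],
) -> tuple[list[FrameSequence], np.ndarray]:
    """Estimate and subtract the static fixed pattern shared by all
    illuminations.

    The pattern is the per-pixel median across illumination-averaged frames
    after removing each frame's mean (the scene changes with illumination
    angle, the pattern does not). Requires at least 3 distinct
    illuminations, below which scene and pattern are not separable.
    Corrected repeats plus the pattern reproduce the originals exactly.
    """
    if len(seqs) < 3:
        raise ValueError("need >= 3 distinct illuminations to identify the static pattern")
    means = np.stack([average_frames(s) for s in seqs])
    centred = means - means.mean(axis=(1, 2), keepdims=True)
    pattern = np.median(centred, axis=0)
    corrected = [
        FrameSequence(
            repeats=s.repeats - pattern,
            illumination_id=s.illumination_id,
            z_um=s.z_um,
            metadata=dict(s.metadata),
        )
        for s in seqs
    ]
    return corrected, pattern


def _tenengrad(img: np.ndarray) -> float:
    """Normalized gradient energy (Tenengrad) sharpness score."""
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    denom = float(np.mean(img**2))
    if denom <= 0:
        return 0.0
    return float(np.mean(gx**2 + gy**2) / denom)


def select_sharpest_plane(
    zstack: list[tuple[float, np.ndarray]],
) -> tuple[float, np.ndarray]:
    """Pick the sharpest plane of a z-stack by gradient energy.

    ``zstack`` is a list of ``(z_um, image)`` pairs. Ties resolve to the
    lowest z (deterministic).
    """
    if len(zstack) < 2:
        raise ValueError("need at least 2 planes")
    ordered = sorted(zstack, key=lambda t: t[0])
    scores = [_tenengrad(img) for _, img in ordered]
    best = int(np.argmax(scores))  # argmax takes the first (lowest z) on ties
    return ordered[best][0], ordered[best][1]
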