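"""HDF5 dataset archive and YAML configuration.

One HDF5 file carries a whole acquisition or simulation session:

    root attrs                 optical constants + schema version
    /plan                      frame / led / x_mm / y_mm illumination table
    /wells/<ID>/frames         (n_frames, H, W) float32 intensities
    /wells/<ID>/k_eff          (n_frames, 2) effective wavevectors, 1/um
    /wells/<ID>/repeats        optional (n_frames, n_repeats, H, W)
    /calibration/k_effective   optional (n_frames, n_tiles, 2)
    /recon/<ID>/...            amplitude, phase, pupil, residuals, delta_z

`validate_archive` checks the schema and returns a list of violations
(empty means valid); validation is a pure read and hence a fixpoint.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import GeometryError, IlluminationPlan, LEDGrid, OpticalConfig, WellLayout
from .raytrace import MeniscusModel
from .simulate import FPMDataset

__all__ = [
    "SCHEMA_VERSION",
    "load_config",
    "save_config",
    "write_archive",
    "read_well",
    "write_recon",
    "validate_archive",
]

SCHEMA_VERSION = "1.0"


# --------------------------------------------------------------------------
# YAML configuration


def load_config(path: str | Path) -> dict:
    """Load optical/layout/meniscus configuration from YAML (or JSON).

    Returns a dict with keys ``optics`` (OpticalConfig), ``layout``
    (WellLayout), ``meniscus`` (MeniscusModel or None) and ``led``
    (dict of LED-grid parameters). Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"optics", "layout", "meniscus", "led"}
    extra = set(raw) - known
    if extra:
        raise GeometryError(f"unknown config sections: {sorted(extra)}")
    cfg = OpticalConfig(**raw.get("optics", {}))
    layout = WellLayout(**raw.get("layout", {}))
    meniscus = MeniscusModel(**raw["meniscus"]) if "meniscus" in raw else None
    led = {"led_pitch_mm": 3.0, "height_mm": 33.0, "emitter_size_um": 250.0}
    led.update(raw.get("led", {}))
    return {"optics": cfg, "layout": layout, "meniscus": meniscus, "led": led}


def save_config(path: str | Path, optics: OpticalConfig, layout: WellLayout, meniscus: MeniscusModel | None = None, led: dict | None = None) -> None:
    doc: dict = {
        "optics": {k: list(v) if isinstance(v, tuple) else v for k, v in dataclasses.asdict(optics).items()},
        "layout": dataclasses.asdict(layout),
    }
    if meniscus is not None:
        doc["meniscus"] = dataclasses.asdict(meniscus)
    if led is not None:
        doc["led"] = led
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# --------------------------------------------------------------------------
# HDF5 archive


def _write_attrs(h: h5py.File, cfg: OpticalConfig) -> None:
    h.attrs["schema_version"] = SCHEMA_VERSION
    h.attrs["units"] = "lengths: mm at plate scale, um at object scale; k: 1/um"
    for k, v in dataclasses.asdict(cfg).items():
        h.attrs[f"optics.{k}"] = v


def read_optics(h: h5py.File) -> OpticalConfig:
    kw = {}
    for key, v in h.attrs.items():
        if key.startswith("optics."):
            name = key[len("optics.") :]
            if name == "fov_mm":
                v = tuple(float(x) for x in v)
            elif name in ("upsample",):
                v = int(v)
            else:
                v = float(v)
            kw[name] = v
    return OpticalConfig(**kw)


def write_archive(
    path: str | Path,
    cfg: OpticalConfig,
    wells: dict[str, FPMDataset],
    plan: IlluminationPlan | None = None,
    grid: LEDGrid | None = None,
    repeats: dict[str, np.ndarray] | None = None,
    k_effective_tiles: np.ndarray | None = None,
) -> None:
    """Write a dataset archive; overwrites any existing file atomically."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with h5py.File(tmp, "w") as h:
        _write_attrs(h, cfg)
        if plan is not None and grid is not None:
            g = h.create_group("plan")
            rows = [
                (f, led, grid.positions_mm[led][0], grid.positions_mm[led][1])
                for f, pat in enumerate(plan.patterns)
                for led in sorted(pat)
            ]
            arr = np.array(rows, dtype=float)
            g.create_dataset("frame", data=arr[:, 0].astype(np.int64))
            g.create_dataset("led", data=arr[:, 1].astype(np.int64))
            g.create_dataset("x_mm", data=arr[:, 2])
            g.create_dataset("y_mm", data=arr[:, 3])
            g.attrs["source_separation_m"] = plan.source_separation_m
        for wid, ds in wells.items():
            g = h.create_group(f"wells/{wid}")
            g.create_dataset("frames", data=ds.frames.astype(np.float32))
            g.create_dataset("k_eff", data=ds.k_eff)
            for k, v in ds.provenance.items():
                if isinstance(v, (int, float, str, bool)):
                    g.attrs[f"provenance.{k}"] = v
            if repeats and wid in repeats:
                g.create_dataset("repeats", data=np.asarray(repeats[wid], dtype=np.float32))
        if k_effective_tiles is not None:
            h.create_dataset("calibration/k_effective", data=k_effective_tiles)
    tmp.replace(path)


def plan_to_csv(path: str | Path, plan: IlluminationPlan, grid: LEDGrid) -> None:
    """Export the illumination plan as a frame,led,x_mm,y_mm CSV table."""
    lines = ["frame,led,x_mm,y_mm"]
    for f, pat in enumerate(plan.patterns):
        for led in sorted(pat):
            x, y = grid.positions_mm[led]
            lines.append(f"{f},{led},{x:.3f},{y:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_well(path: str | Path, well: str) -> FPMDataset:
    with h5py.File(path, "r") as h:
        if f"wells/{well}" not in h:
            raise KeyError(f"well {well!r} not in archive")
        g = h[f"wells/{well}"]
        cfg = read_optics(h)
        prov = {k[len("provenance.") :]: v for k, v in g.attrs.items() if k.startswith("provenance.")}
        return FPMDataset(
            frames=g["frames"][...].astype(float),
            k_eff=g["k_eff"][...],
            cfg=cfg,
            provenance=prov,
        )


def write_recon(path: str | Path, well: str, result) -> None:
    """Store a ReconResult under /recon/<well>; re-runs overwrite atomically."""
    with h5py.File(path, "a") as h:
        key = f"recon/{well}"
        if key in h:
            del h[key]
        g = h.create_group(key)
        g.create_dataset("amplitude", data=np.abs(result.object.values).astype(np.float32))
        g.create_dataset("phase", data=np.angle(result.object.values).astype(np.float32))
        g.create_dataset("pupil_amplitude", data=np.abs(result.pupil.values).astype(np.float32))
        g.create_dataset("pupil_phase", data=np.angle(result.pupil.values).astype(np.float32))
        g.create_dataset("residuals", data=result.residuals)
        g.attrs["object_pixel_um"] = result.object.pixel_um
        if result.delta_z_hat_um is not None:
            g.create_dataset("delta_z", data=float(result.delta_z_hat_um))


def validate_archive(path: str | Path) -> list[str]:
    """Schema check; returns the list of violations (empty = valid)."""
    problems: list[str] = []
    try:
        h = h5py.File(path, "r")
    except OSError as e:
        return [f"unreadable file: {e}"]
    with h:
        if "schema_version" not in h.attrs:
            problems.append("missing schema_version attribute")
        if not any(k.startswith("optics.") for k in h.attrs):
            problems.append("missing optics.* attributes")
        if "wells" in h:
            for wid, g in h["wells"].items():
                if "frames" not in g:
                    problems.append(f"wells/{wid}: missing frames")
                    continue
                if "k_eff" not in g:
                    problems.append(f"wells/{wid}: missing k_eff")
                    continue
                nf = g["frames"].shape[0]
                nk = g["k_eff"].shape[0]
                if nf != nk:
                    problems.append(
                        f"wells/{wid}: frame count {nf} != k_eff count {nk}"
                    )
                if g["frames"].ndim != 3:
                    problems.append(f"wells/{wid}: frames must be 3-D")
    return problems
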