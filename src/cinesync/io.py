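"""Stack container and NIfTI + JSON-sidecar readers/writers.

The interchange layout is one NIfTI volume per slice position with axes
(rows, cols, time), accompanied by a ``stack.json`` sidecar carrying the
acquisition geometry (temporal resolution, pixel spacing, slice thickness,
apex-to-base slice order).  A single 4D NIfTI with a declared slice axis is
accepted as an equivalent input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Used when a sidecar omits dt_ms (typical reconstructed real-time resolution).
DEFAULT_DT_MS = 36.0
DEFAULT_PIXEL_MM = (1.9, 2.8)

SIDECAR_NAME = "stack.json"


@dataclass
class RealTimeStack:
    """Multi-slice real-time acquisition: one 2D time series per slice position.

    ``slices[s]`` has shape (n_frames_s, rows, cols); slice order is
    apex -> base.  Frame counts may differ between slices; in-plane
    dimensions may not.
    """

    slices: list[np.ndarray]
    dt_ms: float
    pixel_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self):
        if len(self.slices) < 1:
            raise ValueError("stack needs at least one slice")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        shapes = {s.shape[1:] for s in self.slices}
        if len(shapes) > 1:
            bad = [i for i, s in enumerate(self.slices) if s.shape[1:] != self.slices[0].shape[1:]]
            raise ValueError(f"inconsistent in-plane shapes in slices {bad}: {sorted(shapes)}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def frame_counts(self) -> list[int]:
        return [s.shape[0] for s in self.slices]

    @property
    def grid(self) -> tuple[int, int]:
        return self.slices[0].shape[1:]

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm[0] * self.pixel_mm[1]


def _affine(pixel_mm, slice_thickness_mm) -> np.ndarray:
    return np.diag([pixel_mm[0], pixel_mm[1], slice_thickness_mm, 1.0])


def save_stack(stack: RealTimeStack, out_dir: str | Path) -> Path:
    """Write one (rows, cols, time) NIfTI per slice plus a geometry sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(stack.pixel_mm, stack.slice_thickness_mm)
    for s, frames in enumerate(stack.slices):
        vol = np.ascontiguousarray(np.moveaxis(frames, 0, -1))  # rows, cols, time
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), out / f"slice_{s:03d}.nii")
    sidecar = {
        "dt_ms": stack.dt_ms,
        "pixel_mm": list(stack.pixel_mm),
        "slice_thickness_mm": stack.slice_thickness_mm,
        "n_slices": stack.n_slices,
        "frame_counts": stack.frame_counts,
        "slice_order": "apex_to_base",
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return out


def _load_sidecar(path: Path) -> dict:
    sidecar_path = (path if path.is_dir() else path.parent) / SIDECAR_NAME
    if sidecar_path.exists():
        return json.loads(sidecar_path.read_text())
    return {}


def _fill_geometry(meta: dict) -> tuple[float, tuple[float, float], float]:
    if "dt_ms" not in meta:
        warnings.warn(f"sidecar missing dt_ms; assuming {DEFAULT_DT_MS} ms", stacklevel=3)
    dt = float(meta.get("dt_ms", DEFAULT_DT_MS))
    if "pixel_mm" not in meta:
        warnings.warn(f"sidecar missing pixel_mm; assuming {DEFAULT_PIXEL_MM} mm", stacklevel=3)
    px = tuple(meta.get("pixel_mm", DEFAULT_PIXEL_MM))
    if "slice_thickness_mm" not in meta:
        warnings.warn("sidecar missing slice_thickness_mm; assuming 8 mm", stacklevel=3)
    thick = float(meta.get("slice_thickness_mm", 8.0))
    return dt, px, thick


def load_stack(path: str | Path, slice_axis: int = 2) -> RealTimeStack:
    """Load a stack from a per-slice directory or a single 4D volume.

    Directories must contain ``slice_*.nii[.gz]`` files (lexicographic order =
    apex to base) and optionally ``stack.json``; missing geometry falls back to
    documented defaults with a warning.  A 4D NIfTI file is split along
    ``slice_axis`` (after the two in-plane axes, default axis 2 of
    rows x cols x slices x time).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("slice_*.nii")) + sorted(path.glob("slice_*.nii.gz"))
        if not files:
            raise FileNotFoundError(f"no slice_*.nii[.gz] volumes found in {path}")
        meta = _load_sidecar(path)
        dt, px, thick = _fill_geometry(meta)
        slices = []
        for f in files:
            vol = np.asarray(nib.load(f).dataobj)
            if vol.ndim != 3:
                raise ValueError(f"{f.name}: expected a 3D (rows, cols, time) volume, got {vol.ndim}D")
            slices.append(np.moveaxis(vol, -1, 0))
        return RealTimeStack(slices=slices, dt_ms=dt, pixel_mm=px, slice_thickness_mm=thick)

    vol = np.asarray(nib.load(path).dataobj)
    if vol.ndim != 4:
        raise ValueError(f"{path.name}: expected a 4D volume, got {vol.ndim}D")
    meta = _load_sidecar(path)
    dt, px, thick = _fill_geometry(meta)
    vol = np.moveaxis(vol, slice_axis, 0)  # slices, rows, cols, time
    slices = [np.moveaxis(vol[s], -1, 0) for s in range(vol.shape[0])]
    return RealTimeStack(slices=slices, dt_ms=dt, pixel_mm=px, slice_thickness_mm=thick)


def save_masks(masks: np.ndarray, pixel_mm, slice_thickness_mm, out_path: str | Path) -> Path:
    """Write a (slices, frames, rows, cols) boolean mask stack as 4D NIfTI."""
    out_path = Path(out_path)
    vol = np.ascontiguousarray(np.moveaxis(np.moveaxis(masks, 1, -1), 0, 2))  # rows, cols, slices, time
    nib.save(nib.Nifti1Image(vol.astype(np.uint8), _affine(pixel_mm, slice_thickness_mm)), out_path)
    return out_path


def load_masks(path: str | Path) -> np.ndarray:
    """Inverse of :func:`save_masks`: returns (slices, frames, rows, cols) bool."""
    vol = np.asarray(nib.load(path).dataobj)
    if vol.ndim != 4:
        raise ValueError("mask volume must be 4D (rows, cols, slices, time)")
    return np.moveaxis(np.moveaxis(vol, 2, 0), -1, 1).astype(bool)


def save_cine(data: np.ndarray, pixel_mm, slice_thickness_mm, out_path: str | Path,
              sidecar: dict | None = None) -> Path:
    """Write a synchronized (slices, time, rows, cols) cine as a 4D NIfTI.

    Stored as rows x cols x slices x time with a JSON provenance sidecar
    next to it when given.
    """
    out_path = Path(out_path)
    vol = np.ascontiguousarray(np.transpose(data, (2, 3, 0, 1)))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(pixel_mm, slice_thickness_mm)), out_path)
    if sidecar is not None:
        out_path.with_suffix(out_path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return out_path
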