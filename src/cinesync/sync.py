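"""Cross-slice synchronization of single-cycle cines.

Each slice contributes one R-R interval (ED..ED inclusive with a marked ES).
The systolic limb (ED..ES) and diastolic limb (ES..ED) are temporally
down-sampled, independently per limb, to the across-slice minimum frame
counts, by per-pixel linear interpolation along time on an
endpoint-inclusive uniform grid.  ED frames then align at index 0 (and the
final index) and ES at a common index in every slice, without ever sharing
frames between heartbeats or reordering consecutively acquired frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SyncError


@dataclass
class SliceCine:
    """One slice's R-R interval: frames ED..ED inclusive, ES at ``es_offset``."""

    slice_index: int
    frames: np.ndarray  # (n, rows, cols)
    es_offset: int
    source_frames: tuple[int, int] | None = None  # global half-open provenance

    def __post_init__(self):
        n = len(self.frames)
        if not (0 < self.es_offset < n - 1):
            raise ValueError(
                f"slice {self.slice_index}: es_offset {self.es_offset} must lie "
                f"strictly inside the interval of {n} frames"
            )

    @property
    def n_sys(self) -> int:
        return self.es_offset + 1

    @property
    def n_dia(self) -> int:
        return len(self.frames) - self.es_offset


@dataclass
class SynchronizedCine:
    """Slices x time cine with ED at index 0 and ES at ``n_sys - 1`` everywhere.

    Time length is ``n_sys + n_dia - 1``: the ES frame is shared between the
    systolic and diastolic limbs and stored once; the trailing ED duplicate is
    kept so the interval bounds are unambiguous (drop it for cyclic playback).
    """

    data: np.ndarray  # (slices, time, rows, cols)
    n_sys: int
    n_dia: int
    pixel_mm: tuple[float, float]
    slice_thickness_mm: float
    dt_ms: float | None = None
    sample_times: list[dict] | None = None  # per-slice provenance

    @property
    def ed_index(self) -> int:
        return 0

    @property
    def es_index(self) -> int:
        return self.n_sys - 1

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def split_intervals(cine: SliceCine) -> tuple[np.ndarray, np.ndarray]:
    """Split into systolic (ED..ES) and diastolic (ES..ED) limbs, both inclusive.

    The ES frame belongs to both limbs; concatenating the limbs minus one
    shared ES frame reproduces the input exactly.
    """
    sys_limb = cine.frames[: cine.es_offset + 1]
    dia_limb = cine.frames[cine.es_offset:]
    return sys_limb, dia_limb


def resample_time(frames: np.ndarray, n_target: int) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample a frame sequence along time by per-pixel linear interpolation.

    Output frame j is sampled at source time ``j * (L - 1) / (n_target - 1)``
    (endpoint-inclusive uniform grid over L input frames); each pixel is
    linearly interpolated between its two bracketing source frames, and the
    first and last output frames are the first and last input frames exactly
    (bit-equal).  Only down-sampling (or the identity) is in scope.

    Returns (resampled frames, source sample times).
    """
    frames = np.asarray(frames)
    length = len(frames)
    if n_target < 2 or length < 2:
        raise ValueError("need n_target >= 2 and at least 2 input frames")
    if n_target > length:
        raise ValueError(
            f"temporal up-sampling not supported: n_target {n_target} > {length} frames"
        )
    times = np.arange(n_target) * (length - 1) / (n_target - 1)
    i0 = np.floor(times).astype(int)
    w = times - i0
    # exact grid hits (including both endpoints) copy source frames bit-exactly
    dtype = frames.dtype if np.issubdtype(frames.dtype, np.floating) else np.float64
    out = np.empty((n_target,) + frames.shape[1:], dtype=dtype)
    for j in range(n_target):
        if w[j] == 0.0:
            out[j] = frames[i0[j]]
        else:
            out[j] = (1.0 - w[j]) * frames[i0[j]].astype(np.float64) \
                + w[j] * frames[i0[j] + 1].astype(np.float64)
    return out, times


def synchronize(slice_cines: list[SliceCine], pixel_mm=(1.0, 1.0),
                slice_thickness_mm: float = 1.0, dt_ms: float | None = None) -> SynchronizedCine:
    """Align R-R intervals across slices onto a common ED/ES time grid.

    N_sys and N_dia are the across-slice minima of the systolic and diastolic
    frame counts; each slice's limbs are resampled independently to those
    counts and rejoined on the shared ES frame, so every slice has ED at
    index 0 (and the final index) and ES at index N_sys - 1.  Slice order
    (apex to base) is preserved.
    """
    if len(slice_cines) < 2:
        raise SyncError("synchronization needs at least two slice positions")
    shapes = {c.frames.shape[1:] for c in slice_cines}
    if len(shapes) > 1:
        raise SyncError(f"inconsistent in-plane geometry across slices: {sorted(shapes)}")
    for c in slice_cines:
        if c.n_sys < 2 or c.n_dia < 2:
            raise SyncError(
                f"slice {c.slice_index}: limb with fewer than 2 frames "
                f"(n_sys={c.n_sys}, n_dia={c.n_dia})"
            )
    n_sys = min(c.n_sys for c in slice_cines)
    n_dia = min(c.n_dia for c in slice_cines)

    stacked = []
    provenance = []
    for c in slice_cines:
        sys_limb, dia_limb = split_intervals(c)
        sys_rs, sys_t = resample_time(sys_limb, n_sys)
        dia_rs, dia_t = resample_time(dia_limb, n_dia)
        joined = np.concatenate([sys_rs, dia_rs[1:]])  # ES frame stored once
        stacked.append(joined)
        offset = 0 if c.source_frames is None else c.source_frames[0]
        provenance.append({
            "slice": c.slice_index,
            "source_frames": list(c.source_frames) if c.source_frames else None,
            "systolic_sample_times": (sys_t + offset).tolist(),
            "diastolic_sample_times": (dia_t + c.es_offset + offset).tolist(),
        })
    return SynchronizedCine(
        data=np.stack(stacked),
        n_sys=n_sys,
        n_dia=n_dia,
        pixel_mm=tuple(pixel_mm),
        slice_thickness_mm=slice_thickness_mm,
        dt_ms=dt_ms,
        sample_times=provenance,
    )


def as_slice_cines(cine: SynchronizedCine) -> list[SliceCine]:
    """View a synchronized cine as per-slice cines (for re-synchronization)."""
    return [
        SliceCine(slice_index=s, frames=cine.data[s], es_offset=cine.es_index)
        for s in range(cine.n_slices)
    ]
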