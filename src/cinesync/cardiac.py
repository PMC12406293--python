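"""Cardiac gating from the LV area curve.

Within the respiratory-gated consecutive frames, the left-ventricular blood
pool is segmented, its cross-sectional area computed per frame, and the
end-diastolic / end-systolic timeframes found by two rules:

* ED: a timeframe whose LV area is strictly larger than that of its
  ``window`` (default 3) nearest frames in each direction;
* ES: the timeframe with the smallest LV area between two consecutive EDs.

One R-R interval is then selected as a (ED, ES, ED) triple.  Automated
detections can be compared against manual ones via the timeframe difference
dT = T_automatic - T_manual (mean and SD per phase).

Segmentation is a pluggable contract (any callable mapping frames to binary
masks); the bundled :class:`ReferenceSegmenter` is an intensity-based
segmenter warranted only for bright-blood phantom-like contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from skimage.filters import threshold_multiotsu
from skimage.measure import label

from .errors import NoRRIntervalError, SegmentationError

DEFAULT_ED_WINDOW = 3
#: Matching window (frames) for pairing automated with manual detections;
#: well under half a cardiac period at exercise heart rates.
DEFAULT_MATCH_WINDOW = 5


@dataclass
class LvAreaSeries:
    """Cross-sectional LV area per frame over a consecutive frame interval.

    ``frames`` is the half-open global frame interval the areas belong to, so
    detections can be reported in global frame coordinates.
    """

    frames: tuple[int, int]
    area_mm2: np.ndarray
    pixel_area_mm2: float

    def __post_init__(self):
        self.area_mm2 = np.asarray(self.area_mm2, dtype=float)
        if len(self.area_mm2) != self.frames[1] - self.frames[0]:
            raise ValueError("area series length must match the frame interval")
        if np.any(self.area_mm2 < 0):
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return len(self.area_mm2)


@dataclass(frozen=True)
class RRInterval:
    """One cardiac cycle: two consecutive ED frames and the enclosed ES."""

    ed_start: int
    es: int
    ed_end: int

    def __post_init__(self):
        if not (self.ed_start < self.es < self.ed_end):
            raise ValueError(f"require ed_start < es < ed_end, got "
                             f"({self.ed_start}, {self.es}, {self.ed_end})")
        if self.n_sys < 2 or self.n_dia < 2:
            raise ValueError("each limb of the R-R interval needs >= 2 frames")

    @property
    def n_sys(self) -> int:
        """Systolic frame count, ED..ES inclusive."""
        return self.es - self.ed_start + 1

    @property
    def n_dia(self) -> int:
        """Diastolic frame count, ES..ED inclusive."""
        return self.ed_end - self.es + 1


@dataclass
class PhaseAgreement:
    """dT = T_automatic - T_manual statistics for one cardiac phase."""

    deltas: np.ndarray
    unmatched_auto: int
    unmatched_manual: int

    @property
    def n(self) -> int:
        return len(self.deltas)

    @property
    def mean(self) -> float:
        return float(np.mean(self.deltas)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        """Sample SD of dT (0 for a single pair, NaN for none)."""
        if self.n == 0:
            return float("nan")
        if self.n == 1:
            return 0.0
        return float(np.std(self.deltas, ddof=1))


@dataclass
class DetectionComparison:
    """Automated-vs-manual agreement for ED and ES detections."""

    ed: PhaseAgreement
    es: PhaseAgreement


class ReferenceSegmenter:
    """Intensity-based LV segmenter for phantom-like bright-blood contrast.

    Thresholds each frame inside a circular search region with a 3-class
    multi-Otsu split (background < myocardium < blood), keeps the largest
    connected component of the top class, and fills holes.  The ``epicardial``
    mode keeps the component above the lower threshold that contains the
    blood pool, yielding the epicardial region (myocardium + cavity).

    Parameters
    ----------
    center_px, radius_px : optional circular search region (pixel units);
        defaults to the image centre with radius min(rows, cols)/3.
    """

    def __init__(self, center_px: tuple[float, float] | None = None,
                 radius_px: float | None = None):
        self.center_px = center_px
        self.radius_px = radius_px

    def _region(self, shape):
        rows, cols = shape
        cy, cx = self.center_px if self.center_px is not None else (rows / 2, cols / 2)
        rad = self.radius_px if self.radius_px is not None else min(rows, cols) / 3
        yy, xx = np.ogrid[:rows, :cols]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2

    @staticmethod
    def _largest_component(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return mask
        lab = label(mask, connectivity=1)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        return lab == counts.argmax()

    def _segment_frame(self, frame: np.ndarray, region: np.ndarray, epicardial: bool):
        vals = frame[region]
        if vals.max() - vals.min() < 1e-9:
            return np.zeros(frame.shape, dtype=bool)
        try:
            t_lo, t_hi = threshold_multiotsu(vals, classes=3, nbins=128)
        except ValueError:  # fewer distinct values than classes
            return np.zeros(frame.shape, dtype=bool)
        blood = self._largest_component((frame >= t_hi) & region)
        blood = scipy.ndimage.binary_fill_holes(blood)
        if not epicardial:
            return blood
        if not blood.any():
            return blood
        above = (frame >= t_lo) & region
        lab = label(above, connectivity=1)
        cy, cx = scipy.ndimage.center_of_mass(blood)
        blood_label = lab[int(round(cy)), int(round(cx))]
        if blood_label == 0:
            return scipy.ndimage.binary_fill_holes(blood)
        return scipy.ndimage.binary_fill_holes(lab == blood_label)

    def __call__(self, frames: np.ndarray) -> np.ndarray:
        return self.segment(frames, epicardial=False)

    def segment(self, frames: np.ndarray, epicardial: bool = False) -> np.ndarray:
        if len(frames) == 0:
            raise ValueError("frames must be non-empty")
        region = self._region(frames.shape[1:])
        masks = np.stack([self._segment_frame(f, region, epicardial) for f in frames])
        n_empty = int((~masks.any(axis=(1, 2))).sum())
        if n_empty > 0.5 * len(frames):
            raise SegmentationError(
                f"{type(self).__name__}: empty segmentation in {n_empty} of "
                f"{len(frames)} frames"
            )
        return masks


def segment_lv(frames: np.ndarray, segmenter=None) -> np.ndarray:
    """Segment the LV blood pool in every frame.

    ``segmenter`` is any callable mapping (n, rows, cols) frames to (n, rows,
    cols) boolean masks; user-supplied mask volumes therefore bypass
    segmentation by being passed through a trivial callable.  Defaults to
    :class:`ReferenceSegmenter`.
    """
    if len(frames) == 0:
        raise ValueError("frames must be non-empty")
    segmenter = segmenter if segmenter is not None else ReferenceSegmenter()
    masks = np.asarray(segmenter(frames)).astype(bool)
    if masks.shape != frames.shape:
        raise SegmentationError(
            f"segmenter returned shape {masks.shape}, expected {frames.shape}"
        )
    n_empty = int((~masks.any(axis=(1, 2))).sum())
    if n_empty > 0.5 * len(frames):
        raise SegmentationError(
            f"{getattr(segmenter, '__name__', type(segmenter).__name__)}: "
            f"empty segmentation in {n_empty} of {len(frames)} frames"
        )
    return masks


def area_series(masks: np.ndarray, pixel_area_mm2: float,
                frames: tuple[int, int] | None = None) -> LvAreaSeries:
    """LV cross-sectional area per frame: pixel count x pixel area."""
    masks = np.asarray(masks)
    if frames is None:
        frames = (0, len(masks))
    areas = masks.reshape(len(masks), -1).sum(axis=1) * pixel_area_mm2
    return LvAreaSeries(frames=frames, area_mm2=areas, pixel_area_mm2=pixel_area_mm2)


def detect_ed(series: LvAreaSeries, window: int = DEFAULT_ED_WINDOW) -> np.ndarray:
    """ED frames: area strictly larger than the `window` nearest frames each way.

    Only indices with a full window on both sides are eligible.  A plateau of
    equal maxima defeats the strict rule at every plateau member; this is
    flagged with a warning rather than silently picking one.  Returns global
    frame indices (ascending).  Raises :class:`NoRRIntervalError` when fewer
    than two EDs are found, since no R-R interval can then be formed.
    """
    a = series.area_mm2
    n = len(a)
    if n <= 2 * window:
        raise NoRRIntervalError(
            f"series of {n} frames is too short for ED detection with window {window}"
        )
    detections = []
    plateau_suspects = 0
    for i in range(window, n - window):
        neigh = np.concatenate([a[i - window:i], a[i + 1:i + window + 1]])
        if np.all(a[i] > neigh):
            detections.append(i)
        elif np.all(a[i] >= neigh):
            plateau_suspects += 1
    if plateau_suspects:
        warnings.warn(
            f"{plateau_suspects} frame(s) tie their window maximum (area plateau); "
            "the strict ED rule reports none of them"
        )
    if len(detections) < 2:
        raise NoRRIntervalError(
            f"found {len(detections)} ED frame(s) in {n} gated frames; "
            "two consecutive EDs are required to define an R-R interval"
        )
    return np.asarray(detections) + series.frames[0]


def detect_es(series: LvAreaSeries, ed_indices: np.ndarray) -> np.ndarray:
    """ES frames: the smallest-area timeframe strictly between consecutive EDs.

    Ties break to the earliest frame.  Input and output are global indices.
    """
    ed_indices = np.asarray(ed_indices)
    if len(ed_indices) < 2:
        raise ValueError("need at least two ED indices")
    lo = series.frames[0]
    out = []
    for a_idx, b_idx in zip(ed_indices[:-1], ed_indices[1:]):
        segment = series.area_mm2[a_idx - lo + 1:b_idx - lo]
        if len(segment) == 0:
            raise ValueError(f"no frames between EDs {a_idx} and {b_idx}")
        out.append(a_idx + 1 + int(np.argmin(segment)))  # argmin is earliest tie
    return np.asarray(out)


def select_rr(ed_indices, es_indices, policy: str = "first",
              manual: tuple[int, int, int] | None = None) -> RRInterval:
    """Select one R-R interval.

    ``policy="first"`` returns the earliest valid (ED, ES, ED) triple;
    ``policy="manual"`` validates and returns the user-specified triple.
    """
    if policy == "manual":
        if manual is None:
            raise ValueError("policy 'manual' requires a (ed_start, es, ed_end) triple")
        return RRInterval(*manual)
    if policy != "first":
        raise ValueError(f"unknown policy {policy!r}")
    ed_indices = np.asarray(ed_indices)
    es_indices = np.asarray(es_indices)
    for a, b in zip(ed_indices[:-1], ed_indices[1:]):
        between = es_indices[(es_indices > a) & (es_indices < b)]
        if len(between):
            try:
                return RRInterval(int(a), int(between[0]), int(b))
            except ValueError:
                continue  # limb too short; try the next pair
    raise NoRRIntervalError("no valid (ED, ES, ED) triple among the detections")


def _match_nearest(auto: np.ndarray, manual: np.ndarray, window: int):
    """Greedy one-to-one nearest matching within +/- window frames.

    Pairs are taken in order of increasing |difference| (ties: earlier
    automated index), so each detection matches its nearest available
    counterpart deterministically.
    """
    pairs = []
    for i, t_a in enumerate(auto):
        for j, t_m in enumerate(manual):
            d = t_a - t_m
            if abs(d) <= window:
                pairs.append((abs(d), i, j, d))
    pairs.sort()
    used_a, used_m, deltas = set(), set(), []
    for _, i, j, d in pairs:
        if i in used_a or j in used_m:
            continue
        used_a.add(i)
        used_m.add(j)
        deltas.append(d)
    return np.asarray(deltas, dtype=float), len(auto) - len(used_a), len(manual) - len(used_m)


def compare_detections(auto, manual, window: int = DEFAULT_MATCH_WINDOW) -> PhaseAgreement:
    """dT = T_automatic - T_manual over nearest-matched pairs for one phase.

    Both index lists must be sorted ascending.  Unmatched detections (no
    counterpart within the window) are counted separately and excluded from
    the statistics; empty inputs yield empty statistics.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if np.any(np.diff(auto) < 0) or np.any(np.diff(manual) < 0):
        raise ValueError("detection lists must be sorted ascending")
    deltas, un_a, un_m = _match_nearest(auto, manual, window)
    return PhaseAgreement(deltas=deltas, unmatched_auto=un_a, unmatched_manual=un_m)


def compare_ed_es(auto_ed, manual_ed, auto_es, manual_es,
                  window: int = DEFAULT_MATCH_WINDOW) -> DetectionComparison:
    """Convenience wrapper producing per-phase agreement for ED and ES."""
    return DetectionComparison(
        ed=compare_detections(auto_ed, manual_ed, window),
        es=compare_detections(auto_es, manual_es, window),
    )
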