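"""Image-based respiratory gating from a diaphragm ROI.

A rectangular ROI placed over the diaphragm is reduced to a one-dimensional
respiratory surrogate by spectral embedding (Laplacian eigenmaps on a
symmetric k-nearest-neighbour graph of the per-frame ROI vectors).  The
surrogate is oriented so that maxima correspond to end expiration, strict
local maxima are detected, and the end-expiratory peak with the greatest
number of consecutive timeframes near its extreme is selected for gating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.ndimage
import scipy.signal
import scipy.sparse.csgraph
import scipy.stats
from sklearn.neighbors import kneighbors_graph

from .errors import (
    DisconnectedGraphError,
    NoPeakError,
    OrientationError,
    RoiBoundsError,
    SelectionTooShortError,
)

#: Fraction of the full signal amplitude accepted below a peak ("near its extreme").
DEFAULT_TOLERANCE_FRAC = 0.15
#: Selections shorter than this are unusable for cardiac gating.
DEFAULT_MIN_RUN = 20
#: Breathing faster than 40 /min is not expected: minimum peak separation.
DEFAULT_MIN_PEAK_SEPARATION_S = 1.5
DEFAULT_SMOOTH_WINDOW = 3
#: Lag-1 autocorrelation below this on the embedding suggests a structureless ROI.
LOW_AUTOCORR_THRESHOLD = 0.5


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular diaphragm ROI on one slice, half-open pixel intervals."""

    slice_index: int
    row_range: tuple[int, int]
    col_range: tuple[int, int]

    def __post_init__(self):
        if self.row_range[0] >= self.row_range[1] or self.col_range[0] >= self.col_range[1]:
            raise ValueError("ROI ranges must be non-empty half-open intervals")

    def validate(self, grid: tuple[int, int]) -> None:
        r0, r1 = self.row_range
        c0, c1 = self.col_range
        if r0 < 0 or c0 < 0 or r1 > grid[0] or c1 > grid[1]:
            raise RoiBoundsError(
                f"ROI rows [{r0},{r1}) cols [{c0},{c1}) outside image {grid}"
            )


@dataclass
class RespiratorySignal:
    """1D respiratory surrogate, one scalar per timeframe.

    ``oriented`` is True once the sign convention "peaks = end expiration"
    has been established; ``peaks`` holds detected strict local maxima of the
    smoothed signal (ascending).
    """

    values: np.ndarray
    dt_ms: float
    oriented: bool = False
    peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    smoothed: np.ndarray | None = None

    @property
    def amplitude(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass
class GatedSelection:
    """Consecutive frames near one end-expiratory peak (half-open interval)."""

    peak: int
    frames: tuple[int, int]
    values: np.ndarray

    def __post_init__(self):
        lo, hi = self.frames
        if not (lo <= self.peak < hi):
            raise ValueError("selected interval must contain its peak")
        if len(self.values) != hi - lo:
            raise ValueError("per-frame values must match the interval length")

    @property
    def n_frames(self) -> int:
        return self.frames[1] - self.frames[0]


def extract_roi_matrix(series: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Flatten the ROI of every frame into a (n_frames, n_roi_pixels) matrix.

    Intensities are normalized per matrix to zero mean, unit variance; a
    constant matrix (identical frames, e.g. a static phantom) skips variance
    scaling with a warning.
    """
    roi.validate(series.shape[1:])
    r0, r1 = roi.row_range
    c0, c1 = roi.col_range
    mat = series[:, r0:r1, c0:c1].reshape(series.shape[0], -1).astype(np.float64)
    mat = mat - mat.mean()
    sd = mat.std()
    if sd == 0:
        warnings.warn("ROI is constant across frames and pixels; skipping variance scaling")
        return mat
    return mat / sd


def embed_respiratory_1d(matrix: np.ndarray, k_neighbors: int | None = None,
                         dt_ms: float = 36.0) -> RespiratorySignal:
    """Laplacian-eigenmaps 1D embedding of the per-frame ROI vectors.

    A symmetric binary k-NN graph (Euclidean distances) is built over frames;
    the eigenvector of the normalized graph Laplacian belonging to the
    smallest nonzero eigenvalue is the respiratory coordinate, scaled to unit
    SD.  Deterministic up to a global sign, which is fixed arbitrarily here
    and resolved by :func:`orient_for_expiration`.
    """
    n = matrix.shape[0]
    if k_neighbors is None:
        k_neighbors = max(10, int(round(0.05 * n)))
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} frames, got {n}")

    adj = kneighbors_graph(matrix, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize
    n_comp, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        largest = int(np.bincount(labels).max())
        raise DisconnectedGraphError(largest, n, k_neighbors)

    deg = np.asarray(adj.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    a = adj.toarray()
    l_sym = np.eye(n) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    # dense solve: n is a few hundred frames; only the two lowest pairs needed
    eigvals, eigvecs = scipy.linalg.eigh(l_sym, subset_by_index=[0, 1])
    coord = d_inv_sqrt * eigvecs[:, 1]

    sd = coord.std()
    if sd > 0:
        coord = coord / sd
    if coord[np.argmax(np.abs(coord))] < 0:  # fix arbitrary global sign
        coord = -coord

    if n > 2:
        c0, c1 = coord[:-1], coord[1:]
        denom = c0.std() * c1.std()
        lag1 = float(np.corrcoef(c0, c1)[0, 1]) if denom > 0 else 0.0
        if lag1 < LOW_AUTOCORR_THRESHOLD:
            warnings.warn(
                f"respiratory embedding has low lag-1 autocorrelation ({lag1:.2f}); "
                "the ROI may contain no coherent diaphragm motion"
            )
    return RespiratorySignal(values=coord, dt_ms=dt_ms)


def _supra_median_row_centroid(series: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Row centroid of supra-median ROI intensity per frame (diaphragm position)."""
    r0, r1 = roi.row_range
    c0, c1 = roi.col_range
    patch = series[:, r0:r1, c0:c1].astype(np.float64)
    med = np.median(patch)
    bright = patch > med
    rows = np.arange(r0, r1, dtype=np.float64)
    weights = bright.sum(axis=2)  # (n_frames, n_rows)
    total = weights.sum(axis=1)
    total[total == 0] = 1.0
    return (weights * rows[None, :]).sum(axis=1) / total


def orient_for_expiration(signal: RespiratorySignal, series: np.ndarray, roi: RoiSpec,
                          override_sign: int | None = None) -> RespiratorySignal:
    """Fix the sign so that signal peaks correspond to end expiration.

    Heuristic: the diaphragm/liver is the bright mass in the ROI and sits
    most cranial (smallest row coordinate) at end expiration, so the oriented
    signal must anti-correlate with the supra-median row centroid.  An
    explicit ``override_sign`` (+1 keep, -1 flip) wins over the heuristic.
    """
    if len(signal.values) != series.shape[0]:
        raise ValueError("signal length does not match the series")
    if override_sign is not None:
        if override_sign not in (-1, 1):
            raise ValueError("override_sign must be +1 or -1")
        return RespiratorySignal(values=override_sign * signal.values,
                                 dt_ms=signal.dt_ms, oriented=True)
    centroid = _supra_median_row_centroid(series, roi)
    if centroid.std() == 0 or signal.values.std() == 0:
        raise OrientationError("degenerate centroid or signal; supply override_sign")
    r = float(np.corrcoef(signal.values, centroid)[0, 1])
    if abs(r) < 0.3:
        raise OrientationError(
            f"orientation heuristic correlation |r|={abs(r):.2f} < 0.3; "
            "supply override_sign explicitly"
        )
    sign = -1.0 if r > 0 else 1.0  # peaks = cranial diaphragm = end expiration
    return RespiratorySignal(values=sign * signal.values, dt_ms=signal.dt_ms, oriented=True)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    return scipy.ndimage.uniform_filter1d(values, size=window, mode="reflect")


def find_peaks(signal: RespiratorySignal, smooth_window: int = DEFAULT_SMOOTH_WINDOW,
               min_separation_s: float = DEFAULT_MIN_PEAK_SEPARATION_S) -> RespiratorySignal:
    """Detect strict local maxima of the smoothed oriented signal.

    Minimum peak separation defaults to 1.5 s (a respiratory-rate prior:
    breathing faster than 40 /min is not expected).
    """
    smoothed = _smooth(signal.values, smooth_window)
    distance = max(1, int(round(min_separation_s * 1000.0 / signal.dt_ms)))
    peaks, _ = scipy.signal.find_peaks(smoothed, distance=distance)
    return RespiratorySignal(values=signal.values, dt_ms=signal.dt_ms,
                             oriented=signal.oriented, peaks=peaks, smoothed=smoothed)


def _run_around_peak(values: np.ndarray, peak: int, floor: float) -> tuple[int, int]:
    """Maximal consecutive half-open run containing `peak` with values >= floor."""
    lo = peak
    while lo > 0 and values[lo - 1] >= floor:
        lo -= 1
    hi = peak + 1
    while hi < len(values) and values[hi] >= floor:
        hi += 1
    return lo, hi


def select_end_expiratory_frames(signal: RespiratorySignal,
                                 tolerance_frac: float = DEFAULT_TOLERANCE_FRAC,
                                 min_run: int = DEFAULT_MIN_RUN) -> GatedSelection:
    """Select the end-expiratory peak with the most timeframes near its extreme.

    For every detected peak, the maximal run of consecutive frames whose
    (smoothed) values stay within ``tolerance_frac`` of the full signal
    amplitude below the peak value is computed; the peak with the longest run
    wins (ties: earliest peak).  Runs shorter than ``min_run`` frames are
    rejected — too few timeframes to contain a full R-R interval.
    """
    candidates = rank_selections(signal, tolerance_frac)
    best = candidates[0]
    if best.n_frames < min_run:
        raise SelectionTooShortError(
            f"best end-expiratory run has {best.n_frames} < {min_run} frames; "
            "increase tolerance_frac or acquire more timeframes"
        )
    return best


def rank_selections(signal: RespiratorySignal,
                    tolerance_frac: float = DEFAULT_TOLERANCE_FRAC) -> list[GatedSelection]:
    """All per-peak selections, longest run first (ties: earliest peak).

    This is the ranked list a user would choose from interactively; automated
    pipelines may fall back to later entries when cardiac gating fails on the
    first.
    """
    if signal.peaks is None or len(signal.peaks) == 0:
        raise NoPeakError("no end-expiratory peak detected (run find_peaks first; "
                          "a strictly monotone signal has none)")
    values = signal.smoothed if signal.smoothed is not None else signal.values
    amplitude = float(values.max() - values.min())
    selections = []
    for peak in signal.peaks:
        floor = values[peak] - tolerance_frac * amplitude
        lo, hi = _run_around_peak(values, int(peak), floor)
        selections.append(GatedSelection(peak=int(peak), frames=(lo, hi),
                                         values=values[lo:hi].copy()))
    order = sorted(range(len(selections)),
                   key=lambda i: (-selections[i].n_frames, selections[i].peak))
    return [selections[i] for i in order]


def spearman_vs_reference(signal: RespiratorySignal, reference: np.ndarray) -> float:
    """|Spearman rho| between the surrogate and a reference displacement trace."""
    rho, _ = scipy.stats.spearmanr(signal.values, reference)
    return float(abs(rho))
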