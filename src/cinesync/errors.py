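"""Exception hierarchy for the gating/synchronization pipeline.

Each pipeline stage raises a distinct subclass so that callers (and the CLI)
can attribute a failure to respiratory gating, cardiac gating, synchronization
or analysis without parsing messages.
"""


class CineSyncError(Exception):
    """Base class for all package errors."""


class PhantomSizingError(CineSyncError):
    """Image grid too small to contain the heart plus respiratory excursion."""


class RoiBoundsError(CineSyncError):
    """Diaphragm ROI lies (partly) outside the image bounds."""


class DisconnectedGraphError(CineSyncError):
    """k-NN frame graph is disconnected; the spectral embedding is undefined."""

    def __init__(self, largest_component: int, n_frames: int, k: int):
        self.largest_component = largest_component
        super().__init__(
            f"k-NN graph ({k} neighbours) over {n_frames} frames is "
            f"disconnected; largest connected component has "
            f"{largest_component} frames. Increase k_neighbors."
        )


class OrientationError(CineSyncError):
    """Respiratory signal orientation could not be established heuristically."""


class NoPeakError(CineSyncError):
    """No end-expiratory peak found in the respiratory surrogate."""


class SelectionTooShortError(CineSyncError):
    """Best end-expiratory run is shorter than the minimum usable length."""


class SegmentationError(CineSyncError):
    """LV segmentation produced empty masks on too many frames."""


class NoRRIntervalError(CineSyncError):
    """Fewer than two end-diastolic frames detected; no R-R interval exists."""


class SyncError(CineSyncError):
    """Slice cines cannot be synchronized (e.g. a limb has < 2 frames)."""


class VolumetryError(CineSyncError):
    """Mask stacks inconsistent with slice-summation volumetry."""


class StageError(CineSyncError):
    """Wraps any stage failure with slice index and stage name for run_pipeline."""

    def __init__(self, stage: str, slice_index, cause: Exception):
        self.stage = stage
        self.slice_index = slice_index
        self.cause = cause
        where = "" if slice_index is None else f" (slice {slice_index})"
        super().__init__(f"stage '{stage}'{where}: {cause}")
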