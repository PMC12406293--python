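"""End-to-end pipeline: respiratory gating -> cardiac gating -> synchronization -> analysis.

Every interactive step of the underlying workflow (diaphragm ROI placement,
end-expiratory peak choice, manual ED/ES picks, phase overrides) is expressed
as configuration so the pipeline is scriptable and deterministic for a fixed
config.  Candidate end-expiratory peaks are tried in decreasing run-length
order until cardiac gating finds an R-R interval — the scriptable equivalent
of a user choosing among the suggested timeframe sets; a slice fails only
when every candidate peak fails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardiac, respiratory, sync, volumetrics
from .cardiac import ReferenceSegmenter
from .errors import CineSyncError, NoRRIntervalError, StageError, SyncError
from .io import RealTimeStack, save_cine
from .respiratory import GatedSelection, RoiSpec


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run.

    ``roi_row_range``/``roi_col_range`` place the diaphragm ROI (applied to
    every slice).  ``lv_center_px``/``lv_search_radius_px`` restrict the
    reference segmenter to a circular LV search region.  ``on_slice_failure``
    selects between aborting (default) and skipping slices where no R-R
    interval can be gated; skipped slices are counted in the report.
    """

    roi_row_range: tuple[int, int]
    roi_col_range: tuple[int, int]
    k_neighbors: int | None = None
    tolerance_frac: float = respiratory.DEFAULT_TOLERANCE_FRAC
    min_run: int = respiratory.DEFAULT_MIN_RUN
    smooth_window: int = respiratory.DEFAULT_SMOOTH_WINDOW
    min_peak_separation_s: float = respiratory.DEFAULT_MIN_PEAK_SEPARATION_S
    orientation_override: int | None = None
    #: Successive multipliers on tolerance_frac tried when cardiac gating
    #: fails on every peak at the current band (the scriptable analogue of a
    #: user widening the "near the extreme" band and retrying).
    tolerance_escalation: tuple[float, ...] = (1.0, 1.5, 2.0)
    ed_window: int = cardiac.DEFAULT_ED_WINDOW
    rr_policy: str = "first"
    lv_center_px: tuple[float, float] | None = None
    lv_search_radius_px: float | None = None
    on_slice_failure: str = "abort"  # or "skip"
    output_dir: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


@dataclass
class SliceRecord:
    """Per-slice provenance: what was selected and detected."""

    slice_index: int
    peak: int | None = None
    gated_frames: tuple[int, int] | None = None
    ed_detections: list[int] = field(default_factory=list)
    es_detections: list[int] = field(default_factory=list)
    rr: tuple[int, int, int] | None = None
    failed: bool = False
    failure_reason: str | None = None
    respiratory_signal: np.ndarray | None = None


@dataclass
class PipelineResult:
    cine: sync.SynchronizedCine
    volume_curve: volumetrics.VolumeCurve
    phases: volumetrics.PhaseSet
    phase_masses_g: dict[str, float]
    slice_records: list[SliceRecord]
    used_slices: list[int]
    failed_slices: list[int]
    warnings: list[str]

    def report(self) -> dict:
        """Machine-readable run report (JSON-serializable)."""
        return {
            "n_sys": self.cine.n_sys,
            "n_dia": self.cine.n_dia,
            "used_slices": self.used_slices,
            "failed_slices": self.failed_slices,
            "phases": self.phases.as_dict(),
            "phase_masses_g": self.phase_masses_g,
            "slices": [
                {
                    "slice": r.slice_index,
                    "peak": r.peak,
                    "gated_frames": list(r.gated_frames) if r.gated_frames else None,
                    "ed_detections": [int(i) for i in r.ed_detections],
                    "es_detections": [int(i) for i in r.es_detections],
                    "rr": list(r.rr) if r.rr else None,
                    "failed": r.failed,
                    "failure_reason": r.failure_reason,
                }
                for r in self.slice_records
            ],
            "sample_times": self.cine.sample_times,
            "warnings": self.warnings,
        }


def _gate_slice(frames: np.ndarray, s: int, config: PipelineConfig,
                segmenter, dt_ms: float, pixel_area_mm2: float) -> SliceRecord:
    """Respiratory + cardiac gating for one slice; fills a SliceRecord."""
    record = SliceRecord(slice_index=s)
    roi = RoiSpec(slice_index=s, row_range=config.roi_row_range,
                  col_range=config.roi_col_range)
    try:
        matrix = respiratory.extract_roi_matrix(frames, roi)
        signal = respiratory.embed_respiratory_1d(matrix, config.k_neighbors, dt_ms)
        signal = respiratory.orient_for_expiration(
            signal, frames, roi, override_sign=config.orientation_override)
        signal = respiratory.find_peaks(signal, config.smooth_window,
                                        config.min_peak_separation_s)
        record.respiratory_signal = signal.values
        candidates: list[GatedSelection] = []
        seen = set()
        for factor in config.tolerance_escalation:
            for c in respiratory.rank_selections(signal, factor * config.tolerance_frac):
                if c.n_frames >= config.min_run and c.frames not in seen:
                    seen.add(c.frames)
                    candidates.append(c)
        if not candidates:
            raise NoRRIntervalError(
                f"no end-expiratory run with >= {config.min_run} frames")
    except CineSyncError as exc:
        raise StageError("resp-gate", s, exc) from exc

    last_error: Exception | None = None
    for cand in candidates:
        lo, hi = cand.frames
        try:
            masks = cardiac.segment_lv(frames[lo:hi], segmenter)
            series = cardiac.area_series(masks, pixel_area_mm2, frames=(lo, hi))
            ed = cardiac.detect_ed(series, config.ed_window)
            es = cardiac.detect_es(series, ed)
            rr = cardiac.select_rr(ed, es, policy=config.rr_policy)
        except CineSyncError as exc:
            last_error = exc
            continue
        record.peak = cand.peak
        record.gated_frames = cand.frames
        record.ed_detections = [int(i) for i in ed]
        record.es_detections = [int(i) for i in es]
        record.rr = (rr.ed_start, rr.es, rr.ed_end)
        return record

    record.failed = True
    record.failure_reason = str(last_error) if last_error else "no usable peak"
    return record


def run_pipeline(stack: RealTimeStack, config: PipelineConfig) -> PipelineResult:
    """Run the full synchronization pipeline on a loaded stack.

    Returns the synchronized cine, the LV volume curve with the four analysis
    phases (ED/MS/ES/ERF), per-phase LV mass, and full per-slice provenance.
    Deterministic for fixed stack and config.
    """
    segmenter = ReferenceSegmenter(center_px=config.lv_center_px,
                                   radius_px=config.lv_search_radius_px)
    collected_warnings: list[str] = []
    records: list[SliceRecord] = []
    slice_cines: list[sync.SliceCine] = []

    for s, frames in enumerate(stack.slices):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            record = _gate_slice(frames, s, config, segmenter,
                                 stack.dt_ms, stack.pixel_area_mm2)
        collected_warnings += [f"slice {s}: {w.message}" for w in caught]
        records.append(record)
        if record.failed:
            continue
        ed0, es, ed1 = record.rr
        slice_cines.append(sync.SliceCine(
            slice_index=s,
            frames=frames[ed0:ed1 + 1],
            es_offset=es - ed0,
            source_frames=(ed0, ed1 + 1),
        ))

    failed = [r.slice_index for r in records if r.failed]
    if failed and config.on_slice_failure == "abort":
        raise StageError(
            "cardiac-gate", None,
            NoRRIntervalError(
                f"{len(failed)} of {len(records)} slices failed to yield an "
                f"R-R interval (slices {failed})"))
    if len(slice_cines) < 2:
        raise StageError("sync", None, SyncError(
            f"only {len(slice_cines)} slices gated successfully; need >= 2"))

    try:
        cine = sync.synchronize(slice_cines, pixel_mm=stack.pixel_mm,
                                slice_thickness_mm=stack.slice_thickness_mm,
                                dt_ms=stack.dt_ms)
    except CineSyncError as exc:
        raise StageError("sync", None, exc) from exc

    try:
        n_t = cine.data.shape[1]
        endo = np.stack([segmenter.segment(cine.data[s]) for s in range(cine.n_slices)])
        curve = volumetrics.volume_curve_from_masks(
            endo, stack.pixel_area_mm2, stack.slice_thickness_mm,
            n_sys=cine.n_sys, dt_ms=stack.dt_ms)
        phases = volumetrics.identify_phases(curve)
        masses = {}
        for name, t in phases.as_dict().items():
            epi_t = segmenter.segment(cine.data[:, t], epicardial=True)
            masses[name] = volumetrics.lv_mass(
                epi_t, endo[:, t], stack.pixel_area_mm2, stack.slice_thickness_mm)
    except CineSyncError as exc:
        raise StageError("analyze", None, exc) from exc

    result = PipelineResult(
        cine=cine,
        volume_curve=curve,
        phases=phases,
        phase_masses_g=masses,
        slice_records=records,
        used_slices=[c.slice_index for c in slice_cines],
        failed_slices=failed,
        warnings=collected_warnings,
    )
    if config.output_dir is not None:
        write_outputs(result, stack, Path(config.output_dir))
    return result


def write_outputs(result: PipelineResult, stack: RealTimeStack, out_dir: Path) -> None:
    """Persist the cine (NIfTI), run report (JSON) and analysis tables (CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = result.report()
    save_cine(result.cine.data, stack.pixel_mm, stack.slice_thickness_mm,
              out_dir / "synchronized_cine.nii", sidecar=report["sample_times"] and {
                  "n_sys": result.cine.n_sys, "n_dia": result.cine.n_dia,
                  "sample_times": report["sample_times"]})
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))

    pd.DataFrame({
        "frame": np.arange(len(result.volume_curve.volumes_ml)),
        "volume_ml": result.volume_curve.volumes_ml,
    }).to_csv(out_dir / "volume_curve.csv", index=False)

    rows = [{"phase": k, "frame": v, "lv_mass_g": result.phase_masses_g[k]}
            for k, v in result.phases.as_dict().items()]
    pd.DataFrame(rows).to_csv(out_dir / "phase_table.csv", index=False)

    sig_rows = []
    for r in result.slice_records:
        if r.respiratory_signal is None:
            continue
        lo, hi = r.gated_frames if r.gated_frames else (0, 0)
        for f, v in enumerate(r.respiratory_signal):
            sig_rows.append({"slice": r.slice_index, "frame": f, "value": v,
                             "selected": int(lo <= f < hi)})
    pd.DataFrame(sig_rows).to_csv(out_dir / "respiratory_signal.csv", index=False)
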