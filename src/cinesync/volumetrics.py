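"""Slice-summation LV volumetry, analysis phases, and Bland-Altman agreement.

Volumes use Simpson slice summation (per-slice cross-sectional area x slice
thickness, no basal partial-slice correction); mass is (epicardial -
endocardial) volume times myocardial density.  Because the anatomical mass
of the ventricle is constant over time, the consistency of LV mass across
cardiac phases — end diastole (ED), mid systole (MS), end systole (ES) and
early rapid filling (ERF) — is the validation metric for a synchronized
cine, assessed with Bland-Altman bias and SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import VolumetryError

#: Standard myocardial density in g/mL.
DEFAULT_DENSITY_G_PER_ML = 1.05


@dataclass
class VolumeCurve:
    """LV endocardial volume (mL) per timeframe of a synchronized cine."""

    volumes_ml: np.ndarray
    n_sys: int
    dt_ms: float | None = None

    def __post_init__(self):
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if np.any(self.volumes_ml < 0):
            raise ValueError("volumes must be non-negative")


@dataclass(frozen=True)
class PhaseSet:
    """Timeframe indices of the four analysis phases within one cycle."""

    ed: int
    ms: int
    es: int
    erf: int

    def __post_init__(self):
        if not (self.ed < self.ms < self.es < self.erf):
            raise ValueError(f"phases must be ordered ed < ms < es < erf, got {self}")

    def as_dict(self) -> dict[str, int]:
        return {"ed": self.ed, "ms": self.ms, "es": self.es, "erf": self.erf}


@dataclass
class BlandAltmanResult:
    """Agreement between paired measurements: bias, SD, limits of agreement."""

    bias: float
    sd: float
    loa: tuple[float, float]
    percent_bias: float | None = None
    percent_sd: float | None = None

    def summary(self) -> str:
        s = f"{self.bias:+.2f} ± {self.sd:.2f}"
        if self.percent_bias is not None:
            s += f" ({self.percent_bias:+.0f} ± {self.percent_sd:.0f}%)"
        return s


def lv_volume(endo_masks, pixel_area_mm2: float, slice_thickness_mm: float) -> float:
    """Simpson slice-summation volume (mL) from one mask per slice.

    ``endo_masks`` is a (n_slices, rows, cols) array (or list) of binary
    masks, all belonging to the same timeframe.
    """
    masks = [np.asarray(m) for m in endo_masks]
    missing = [i for i, m in enumerate(masks) if m is None or m.ndim != 2]
    if missing:
        raise VolumetryError(f"missing or non-2D masks for slices {missing}")
    total_mm3 = sum(m.sum() * pixel_area_mm2 * slice_thickness_mm for m in masks)
    return float(total_mm3) / 1000.0


def lv_mass(epi_masks, endo_masks, pixel_area_mm2: float, slice_thickness_mm: float,
            density_g_per_ml: float = DEFAULT_DENSITY_G_PER_ML) -> float:
    """LV myocardial mass (g): (epicardial - endocardial) volume x density.

    The endocardium must lie inside the epicardium; small protrusions are
    clipped by intersection with a warning, and an endocardial excess above
    5% of the epicardial area is treated as a delineation inconsistency.
    """
    epi = [np.asarray(m, dtype=bool) for m in epi_masks]
    endo = [np.asarray(m, dtype=bool) for m in endo_masks]
    if len(epi) != len(endo):
        raise VolumetryError("epicardial and endocardial stacks differ in slice count")
    clipped = []
    for i, (ep, en) in enumerate(zip(epi, endo)):
        outside = int((en & ~ep).sum())
        if outside:
            epi_area = max(int(ep.sum()), 1)
            if outside > 0.05 * epi_area:
                raise VolumetryError(
                    f"slice {i}: endocardium exceeds epicardium by {outside} px "
                    f"(> 5% of epicardial area {epi_area} px)"
                )
            warnings.warn(f"slice {i}: clipping {outside} endocardial px outside the epicardium")
        clipped.append(en & ep)
    v_epi = lv_volume(epi, pixel_area_mm2, slice_thickness_mm)
    v_endo = lv_volume(clipped, pixel_area_mm2, slice_thickness_mm)
    return (v_epi - v_endo) * density_g_per_ml


def identify_phases(curve: VolumeCurve, n_sys: int | None = None,
                    ms: int | None = None, erf: int | None = None) -> PhaseSet:
    """Default analysis-phase conventions on a synchronized volume curve.

    ED is index 0 and ES index ``n_sys - 1`` by the synchronization contract.
    MS defaults to the midpoint of systole; ERF to the frame starting the
    fastest early-filling step (argmax of the forward volume difference on
    frames >= ES).  Both are manually overridable, mirroring an interactive
    phase pick.
    """
    if n_sys is None:
        n_sys = curve.n_sys
    v = curve.volumes_ml
    ed, es = 0, n_sys - 1
    if ms is None:
        ms = int(np.floor((n_sys - 1) / 2 + 0.5))  # midpoint, half-up
    if erf is None:
        diffs = np.diff(v)[es:]  # forward differences on frames >= ES
        if len(diffs) == 0 or np.max(diffs) <= 0:
            raise VolumetryError(
                "flat or non-filling diastolic volume curve; supply erf manually"
            )
        erf = es + int(np.argmax(diffs))
        erf = max(erf, es + 1)  # keep the phase ordering when filling starts at ES
    return PhaseSet(ed=ed, ms=ms, es=es, erf=erf)


def bland_altman(x, y, reference_mean: float | None = None) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Differences d = x - y give bias = mean(d), sd = sample SD(d) and limits
    of agreement bias ± 1.96 sd; with ``reference_mean`` (e.g. the mass at
    rest) the bias and SD are also expressed as a percentage of it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    pb = ps = None
    if reference_mean is not None:
        if reference_mean == 0:
            raise ValueError("reference_mean must be nonzero")
        pb = 100.0 * bias / reference_mean
        ps = 100.0 * sd / reference_mean
    return BlandAltmanResult(bias=bias, sd=sd, loa=(bias - 1.96 * sd, bias + 1.96 * sd),
                             percent_bias=pb, percent_sd=ps)


def volume_curve_from_masks(endo_masks: np.ndarray, pixel_area_mm2: float,
                            slice_thickness_mm: float, n_sys: int,
                            dt_ms: float | None = None) -> VolumeCurve:
    """Volume curve from a (slices, time, rows, cols) endocardial mask stack."""
    masks = np.asarray(endo_masks, dtype=bool)
    vols = [
        lv_volume(masks[:, t], pixel_area_mm2, slice_thickness_mm)
        for t in range(masks.shape[1])
    ]
    return VolumeCurve(volumes_ml=np.asarray(vols), n_sys=n_sys, dt_ms=dt_ms)
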