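"""Volume reconstruction from serial 2 mm sections (truncated-cone rule).

An ablation volume is rebuilt from its per-slice cross-sectional areas by
the truncated-cone (trapezoidal) formula

    V = sum_i (A_i + A_{i+1}) / 2 * d,

with d the slice spacing. The heat-sink deformation is quantified against
an *idealized* ablation: per slice, a half-disc of the maximum ablation
radius r_max (only the vessel-containing half of each section enters the
analysis). The cooling volume is the idealized minus the actual volume,
and the cooling portion expresses it as a percentage of the ablation
volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .errors import DataError, MeasurementError, ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .planimetry import SliceMeasurement

log = logging.getLogger(__name__)

__all__ = [
    "StackReport",
    "frustum_volume",
    "idealized_half_area",
    "cooling_area",
    "cooling_portion",
    "round_half_up",
    "stack_report",
]

#: relative magnitude below which a negative cooling area is clamped silently
_CLAMP_TOL = 1e-6


@dataclass
class StackReport:
    """Per-ablation volume report (vessel-half convention throughout)."""

    ablation_volume_ml: float
    idealized_volume_ml: float
    cooling_volume_ml: float
    cooling_portion_pct: Optional[float]
    n_slices: int
    av_distance_mm: Optional[float] = None
    flow_ml_min: Optional[float] = None
    replicate_id: Optional[str] = None


def frustum_volume(areas: Sequence[float], spacing_mm: float) -> float:
    """Truncated-cone (trapezoidal) volume of an ordered slice-area profile, in ml.

    Parameters
    ----------
    areas
        Cross-sectional areas (mm^2) ordered along the antenna axis.
    spacing_mm
        Uniform slice spacing (mm).
    """
    a = np.asarray(areas, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise MeasurementError("frustum_volume needs at least 2 slice areas")
    if np.any(~np.isfinite(a)):
        raise DataError("frustum_volume: non-finite slice area")
    if np.any(a < 0):
        raise DataError("frustum_volume: negative slice area")
    if spacing_mm <= 0:
        raise ParameterError("frustum_volume: spacing must be > 0")
    # mm^3 -> ml
    return float(np.sum((a[:-1] + a[1:]) / 2.0) * spacing_mm / 1000.0)


def idealized_half_area(r_max_mm: float) -> float:
    """Area (mm^2) of the idealized half-ablation: a half-disc of radius r_max."""
    if not math.isfinite(r_max_mm) or r_max_mm < 0:
        raise DataError("idealized_half_area: r_max must be finite and >= 0")
    return 0.5 * math.pi * r_max_mm * r_max_mm


def cooling_area(measurement: "SliceMeasurement") -> float:
    """Per-slice cooling area: idealized half-disc minus measured vessel-half area.

    Mathematically the half region is contained in the antenna-centred
    half-disc of radius r_max, so the difference is non-negative; values
    below zero can only arise from floating-point noise and are clamped,
    with a warning when the pre-clamp magnitude is not negligible.
    """
    half = getattr(measurement, "half_area_mm2", None)
    ideal = getattr(measurement, "idealized_half_area_mm2", None)
    if half is None or ideal is None or not (math.isfinite(half) and math.isfinite(ideal)):
        raise DataError("cooling_area: half_area_mm2 / idealized_half_area_mm2 not populated")
    raw = ideal - half
    if raw < 0:
        if abs(raw) > _CLAMP_TOL * max(ideal, 1.0):
            log.warning(
                "cooling area clamped to 0 (was %.6g mm^2 at offset %s mm)",
                raw,
                getattr(measurement, "offset_mm", "?"),
            )
        return 0.0
    return raw


def cooling_portion(cooling_volume_ml: float, ablation_volume_ml: float) -> float:
    """Cooling volume as a percentage of the ablation volume (full precision).

    For tabulation the value is conventionally rounded to the nearest
    integer percent; use :func:`round_half_up` for that.
    """
    if ablation_volume_ml <= 0:
        raise DataError("cooling_portion: undefined for ablation volume <= 0")
    return 100.0 * cooling_volume_ml / ablation_volume_ml


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (tabulation rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stack_report(
    slices: Sequence["SliceMeasurement"],
    spacing_mm: float,
    av_distance_mm: Optional[float] = None,
    flow_ml_min: Optional[float] = None,
    replicate_id: Optional[str] = None,
    offset_tol_mm: float = 0.01,
) -> StackReport:
    """Reconstruct the per-ablation volume report from ordered slice measurements.

    ``ablation_volume`` and ``idealized_volume`` are both trapezoidal sums;
    ``cooling_volume`` is their difference, so the additivity invariant
    ``idealized = ablation + cooling`` holds exactly.
    """
    if len(slices) < 2:
        raise MeasurementError("stack_report needs at least 2 slices")
    offsets = np.array([m.offset_mm for m in slices], dtype=float)
    steps = np.diff(offsets)
    if np.any(steps <= 0):
        raise DataError("stack_report: slices must be strictly ordered by offset")
    if np.any(np.abs(steps - spacing_mm) > offset_tol_mm):
        bad = offsets[1:][np.abs(steps - spacing_mm) > offset_tol_mm]
        raise DataError(f"stack_report: non-uniform slice spacing near offsets {bad.tolist()} mm")
    half = [m.half_area_mm2 for m in slices]
    ideal = [m.idealized_half_area_mm2 for m in slices]
    v_abl = frustum_volume(half, spacing_mm)
    v_ideal = frustum_volume(ideal, spacing_mm)
    v_cool = v_ideal - v_abl
    if v_cool < 0:
        if abs(v_cool) > _CLAMP_TOL * max(v_ideal, 1.0):
            log.warning("cooling volume clamped to 0 (was %.6g ml)", v_cool)
        v_cool = 0.0
    portion = cooling_portion(v_cool, v_abl) if v_abl > 0 else None
    return StackReport(
        ablation_volume_ml=v_abl,
        idealized_volume_ml=v_ideal,
        cooling_volume_ml=v_cool,
        cooling_portion_pct=portion,
        n_slices=len(slices),
        av_distance_mm=av_distance_mm,
        flow_ml_min=flow_ml_min,
        replicate_id=replicate_id,
    )
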