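"""Semi-quantitative cooling classification (Types 0–III) and distance profiles.

Each slice is graded by how strongly the vessel deforms the white zone:

* Type 0 (none): the ablation shape is unaffected by the vessel.
* Type I (minor): the boundary is slightly indented towards the vessel.
* Type II (moderate): strong indentation, vessel still partly enclosed.
* Type III (major): strong indentation and the vessel lies outside the
  ablation.

The pictorial scheme is operationalized with two thresholds on the
indentation ratio iota = 1 - r(theta_vessel)/r_max: ``tau_minor``
(default 0.05) separates none from minor, ``tau_moderate`` (default
0.20) marks strong indentation; the enclosure fraction f of the vessel
disc then separates II (0 < f < 1) from III (f = 0). A strongly indented
boundary that still fully encloses the vessel (f = 1) reads as minor:
the deformation has not yet reached the vessel.

Profiles aggregate slice types against the 3D vessel-to-ablation-centre
distance rho = sqrt(d^2 + z^2) (the vessel runs parallel to the antenna,
so its in-slice distance to the centre point grows with |offset z|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParameterError
from .planimetry import SliceMeasurement

__all__ = [
    "CoolingType",
    "TypeProfilePoint",
    "classify_slice",
    "classify_value",
    "type_profile",
    "profile_peak",
]

_F_TOL = 1e-9  # enclosure fractions within this of 0/1 count as exactly 0/1


class CoolingType(IntEnum):
    NONE = 0
    MINOR = 1
    MODERATE = 2
    MAJOR = 3

    @property
    def label(self) -> str:
        return {0: "none", 1: "minor", 2: "moderate", 3: "major"}[int(self)]


@dataclass(frozen=True)
class TypeProfilePoint:
    """Mean cooling type in one rho bin."""

    rho_mm: float
    mean_type: float
    n: int


def _check_taus(tau_minor: float, tau_moderate: float) -> None:
    if not (0.0 < tau_minor < tau_moderate < 1.0):
        raise ParameterError("thresholds must satisfy 0 < tau_minor < tau_moderate < 1")


def classify_value(
    indentation_ratio: float,
    enclosure_fraction: float,
    tau_minor: float = 0.05,
    tau_moderate: float = 0.20,
) -> CoolingType:
    """Grade one (iota, f) pair into a cooling type."""
    _check_taus(tau_minor, tau_moderate)
    iota, f = indentation_ratio, enclosure_fraction
    if not (0.0 <= iota <= 1.0) or not math.isfinite(iota):
        raise DataError(f"indentation ratio {iota!r} outside [0, 1]")
    if not (0.0 <= f <= 1.0) or not math.isfinite(f):
        raise DataError(f"enclosure fraction {f!r} outside [0, 1]")
    if iota < tau_minor:
        return CoolingType.NONE
    if iota < tau_moderate:
        return CoolingType.MINOR
    if f <= _F_TOL:
        return CoolingType.MAJOR
    if f >= 1.0 - _F_TOL:
        return CoolingType.MINOR
    return CoolingType.MODERATE


def classify_slice(
    measurement: SliceMeasurement,
    tau_minor: float = 0.05,
    tau_moderate: float = 0.20,
) -> CoolingType:
    """Grade one measured slice; also stores the type on the measurement."""
    ct = classify_value(
        measurement.indentation_ratio, measurement.enclosure_fraction, tau_minor, tau_moderate
    )
    measurement.cooling_type = int(ct)
    return ct


def type_profile(
    measurements: Iterable[SliceMeasurement],
    bin_width_mm: float = 1.0,
) -> list[TypeProfilePoint]:
    """Bin classified slices by rho and average their cooling types.

    Returns one point per non-empty bin, at the bin centre, sorted by rho.
    """
    if bin_width_mm <= 0:
        raise ParameterError("bin_width_mm must be > 0")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_seen = 0
    for m in measurements:
        n_seen += 1
        if m.cooling_type is None:
            raise DataError("type_profile: slice has no cooling_type (classify first)")
        rho = m.rho_mm
        if rho is None:
            raise DataError("type_profile: slice has no av_distance_mm (cannot compute rho)")
        b = int(math.floor(rho / bin_width_mm))
        sums[b] = sums.get(b, 0.0) + float(m.cooling_type)
        counts[b] = counts.get(b, 0) + 1
    if n_seen == 0:
        raise DataError("type_profile: empty input")
    return [
        TypeProfilePoint(rho_mm=(b + 0.5) * bin_width_mm, mean_type=sums[b] / counts[b], n=counts[b])
        for b in sorted(sums)
    ]


def profile_peak(profile: Sequence[TypeProfilePoint]) -> float:
    """rho (mm) of the profile maximum; the lowest rho wins exact ties."""
    if not profile:
        raise DataError("profile_peak: empty profile")
    means = np.array([p.mean_type for p in profile])
    return float(profile[int(np.argmax(means))].rho_mm)
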