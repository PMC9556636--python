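"""Per-slice 2D planimetry of ablation cross sections.

Conventions
-----------
Coordinates are in mm, already calibrated. The antenna point is the
in-plane origin of each section (it defines the symmetry axis of the
idealized ablation), the simulated vessel lies on the +x axis at the
antenna–vessel distance d. Polygons are ordered vertex lists, implicitly
closed, stored counter-clockwise; the last vertex is not repeated.

The quantitative analysis uses only the vessel-containing half of each
section: the section is clipped to the closed half-plane bounded by the
line through the antenna point perpendicular to the antenna->vessel
direction (points on the line belong to the vessel side). Maximum radius
and azimuthal boundary radii are measured from the antenna point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .errors import GeometryError, ParameterError
from .volumetry import cooling_area as _cooling_area
from .volumetry import idealized_half_area

__all__ = [
    "SliceGeometry",
    "SliceMeasurement",
    "polygon_area",
    "max_radius",
    "vessel_half",
    "boundary_radius_at_azimuth",
    "vessel_enclosure_fraction",
    "measure_slice",
]


@dataclass
class SliceGeometry:
    """One 2 mm cross section: white-zone/red-zone contours plus landmarks.

    ``offset_mm`` is the signed distance along the antenna axis from the
    ablation centre (0 = largest cross section). The red zone contour is
    optional and carried through I/O but excluded from volumetry.
    """

    offset_mm: float
    wz_polygon: np.ndarray
    rz_polygon: Optional[np.ndarray] = None
    antenna_point: np.ndarray = field(default_factory=lambda: np.zeros(2))
    vessel_centre: np.ndarray = field(default_factory=lambda: np.zeros(2))
    vessel_outer_radius_mm: float = 2.5
    vessel_inner_radius_mm: float = 1.5
    scale_mm_per_unit: float = 1.0

    def __post_init__(self) -> None:
        self.wz_polygon = np.asarray(self.wz_polygon, dtype=float)
        if self.rz_polygon is not None:
            self.rz_polygon = np.asarray(self.rz_polygon, dtype=float)
        self.antenna_point = np.asarray(self.antenna_point, dtype=float)
        self.vessel_centre = np.asarray(self.vessel_centre, dtype=float)
        if self.wz_polygon.ndim != 2 or self.wz_polygon.shape[0] < 3 or self.wz_polygon.shape[1] != 2:
            raise GeometryError("wz_polygon must be an (n>=3, 2) vertex array")
        if self.vessel_outer_radius_mm <= 0 or self.vessel_inner_radius_mm <= 0:
            raise ParameterError("vessel radii must be > 0")
        if self.vessel_inner_radius_mm >= self.vessel_outer_radius_mm:
            raise ParameterError("vessel inner radius must be < outer radius")


@dataclass
class SliceMeasurement:
    """Derived per-slice quantities feeding volumetry and classification.

    ``indentation_ratio`` is 1 - r(theta_vessel)/r_max: the fractional
    radial loss of the boundary at the vessel azimuth relative to the
    maximum ablation radius. ``enclosure_fraction`` is the area fraction
    of the vessel disc covered by the white zone.
    """

    offset_mm: float
    wz_area_mm2: float
    r_max_mm: float
    half_area_mm2: float
    idealized_half_area_mm2: float
    cooling_area_mm2: float
    indentation_ratio: float
    enclosure_fraction: float
    cooling_type: Optional[int] = None
    # run metadata, attached by the pipeline for profiles/statistics
    av_distance_mm: Optional[float] = None
    flow_ml_min: Optional[float] = None
    replicate: Optional[int] = None
    run_id: Optional[str] = None

    @property
    def rho_mm(self) -> Optional[float]:
        """3D vessel-to-ablation-centre distance sqrt(d^2 + z^2)."""
        if self.av_distance_mm is None:
            return None
        return math.hypot(self.av_distance_mm, self.offset_mm)


def _as_shapely(polygon: np.ndarray) -> Polygon:
    arr = np.asarray(polygon, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise GeometryError("polygon must be an (n>=3, 2) vertex array")
    if not np.all(np.isfinite(arr)):
        raise GeometryError("polygon has non-finite vertices")
    poly = Polygon(arr)
    if not poly.is_valid:
        raise GeometryError("polygon is self-intersecting or degenerate")
    return poly


def _ring_coords(poly: Polygon) -> np.ndarray:
    xy = np.asarray(poly.exterior.coords, dtype=float)[:-1]
    if not poly.exterior.is_ccw:
        xy = xy[::-1]
    return xy


def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area (mm^2) of a simple polygon, positive regardless of orientation."""
    return float(_as_shapely(polygon).area)


def max_radius(polygon: np.ndarray, origin: np.ndarray) -> float:
    """Maximum boundary distance r_max from ``origin`` (attained at a vertex)."""
    poly = _as_shapely(polygon)
    o = np.asarray(origin, dtype=float)
    if not poly.covers(Point(o)):
        raise GeometryError("max_radius: origin lies outside the polygon")
    arr = np.asarray(polygon, dtype=float)
    return float(np.max(np.hypot(arr[:, 0] - o[0], arr[:, 1] - o[1])))


def vessel_half(polygon: np.ndarray, antenna_point: np.ndarray, vessel_centre: np.ndarray) -> np.ndarray:
    """Clip the section to the vessel-containing half-plane.

    The half-plane is bounded by the line through ``antenna_point``
    perpendicular to the antenna->vessel direction and contains the
    vessel; points on the line belong to the vessel side.
    """
    poly = _as_shapely(polygon)
    a = np.asarray(antenna_point, dtype=float)
    v = np.asarray(vessel_centre, dtype=float)
    u = v - a
    norm = float(np.hypot(*u))
    if norm == 0:
        raise GeometryError("vessel_half: vessel centre coincides with antenna point")
    u = u / norm
    t = np.array([-u[1], u[0]])
    arr = np.asarray(polygon, dtype=float)
    reach = float(np.max(np.hypot(arr[:, 0] - a[0], arr[:, 1] - a[1]))) + norm
    r = 4.0 * reach
    rect = Polygon([a - r * t, a + r * t, a + r * t + r * u, a - r * t + r * u])
    clipped = poly.intersection(rect)
    if clipped.is_empty or clipped.area <= 0:
        raise GeometryError("vessel_half: degenerate clip (no area on the vessel side)")
    if clipped.geom_type == "MultiPolygon":
        warnings.warn("vessel_half: clip produced multiple pieces; keeping the largest")
        clipped = max(clipped.geoms, key=lambda g: g.area)
    return _ring_coords(clipped)


def boundary_radius_at_azimuth(polygon: np.ndarray, origin: np.ndarray, theta: float) -> float:
    """Distance from ``origin`` to the boundary along the ray at angle ``theta``.

    For a polygon star-shaped about ``origin`` the intersection is unique.
    Slightly folded measured contours yield several crossings; the nearest
    is returned with a warning. No crossing at all is a geometry error.
    """
    poly = _as_shapely(polygon)
    o = np.asarray(origin, dtype=float)
    if not poly.covers(Point(o)):
        raise GeometryError("boundary_radius_at_azimuth: origin not inside the polygon")
    arr = np.asarray(polygon, dtype=float)
    reach = 2.0 * (float(np.max(np.hypot(arr[:, 0] - o[0], arr[:, 1] - o[1]))) + 1.0)
    ray = LineString([o, o + reach * np.array([math.cos(theta), math.sin(theta)])])
    inter = poly.exterior.intersection(ray)
    pts: list[np.ndarray] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.is_empty:
            continue
        if geom.geom_type == "Point":
            pts.append(np.asarray(geom.coords[0]))
        else:  # ray collinear with an edge: keep both ends
            pts.extend(np.asarray(c) for c in geom.coords)
    dists = sorted({round(float(np.hypot(*(p - o))), 9) for p in pts if np.hypot(*(p - o)) > 1e-9})
    if not dists:
        raise GeometryError(f"boundary_radius_at_azimuth: no boundary crossing at theta={theta:.4f} rad")
    if len(dists) > 1:
        warnings.warn(
            f"polygon not star-shaped at theta={theta:.4f} rad "
            f"({len(dists)} crossings); using the nearest"
        )
    return float(dists[0])


def vessel_enclosure_fraction(polygon: np.ndarray, vessel_centre: np.ndarray, vessel_outer_radius: float) -> float:
    """Fraction of the vessel disc area covered by the polygon, in [0, 1]."""
    if vessel_outer_radius <= 0:
        raise ParameterError("vessel_enclosure_fraction: radius must be > 0")
    poly = _as_shapely(polygon)
    disc = Point(np.asarray(vessel_centre, dtype=float)).buffer(vessel_outer_radius, quad_segs=128)
    f = poly.intersection(disc).area / disc.area
    return float(min(1.0, max(0.0, f)))


def measure_slice(geometry: SliceGeometry) -> SliceMeasurement:
    """Compute all per-slice planimetry for one section (white zone only).

    The returned measurement has ``cooling_type`` unset; classification is
    a separate step (see :mod:`mwacool.classify`).
    """
    wz = geometry.wz_polygon
    a = geometry.antenna_point
    v = geometry.vessel_centre
    area = polygon_area(wz)
    r_max = max_radius(wz, a)
    half = vessel_half(wz, a, v)
    half_area = polygon_area(half)
    ideal = idealized_half_area(r_max)
    theta_vessel = math.atan2(v[1] - a[1], v[0] - a[0])
    r_vessel = boundary_radius_at_azimuth(wz, a, theta_vessel)
    iota = min(1.0, max(0.0, 1.0 - r_vessel / r_max)) if r_max > 0 else 0.0
    f = vessel_enclosure_fraction(wz, v, geometry.vessel_outer_radius_mm)
    m = SliceMeasurement(
        offset_mm=geometry.offset_mm,
        wz_area_mm2=area,
        r_max_mm=r_max,
        half_area_mm2=half_area,
        idealized_half_area_mm2=ideal,
        cooling_area_mm2=0.0,
        indentation_ratio=iota,
        enclosure_fraction=f,
    )
    m.cooling_area_mm2 = _cooling_area(m)
    return m
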