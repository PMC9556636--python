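"""Synthetic ablation-geometry generator ("phantom") with analytic ground truth.

The phantom emulates the geometry the 3D pipeline is built to analyse: an
ellipsoidal white zone (nominal 3.6 x 3.2 cm, semi-axes a = 18 mm along
the antenna, b = 16 mm radially) deformed on the vessel side by a
heat-sink indentation. In each 2 mm section at axial offset z the white
zone boundary, star-shaped about the antenna point, is

    r(theta, z) = r0(z) * [1 - kappa(z) * exp(-dtheta^2 / (2 sigma_theta^2))] + noise,

with r0(z) = b * sqrt(1 - (z/a)^2) the uncooled ellipse radius and dtheta
the azimuthal offset from the vessel direction. The notch depth couples
flow rate Q and the 3D vessel-to-centre distance rho(z) = sqrt(d^2 + z^2):

    kappa(z) = kappa0 * L(Q; Q50(rho)) * exp(-(rho - rho*)^2 / (2 sigma_rho^2)),
    Q50(rho) = Qc * exp(-rho / rho_c),
    L(Q; Q50) = 1 / (1 + (Q50/Q)^s)   (logistic in log-flow; L(0) = 0).

This reproduces the qualitative behaviour of a single perfused vessel
beside a microwave ablation: no deformation without perfusion, cooling
from minimal flow rates (>= 2 ml/min) where the vessel sits near the
ablation border (rho* = 7.5 mm), and a much higher flow demand (>= 10
ml/min) where the vessel passes the energy-dense ablation centre. It is a
generative stand-in for ex vivo experiments, not a biophysical
heat-transfer model.

Ground truth (half-ablation volume, cooling volume, per-slice cooling
areas and types) is computed by high-resolution numerical integration of
the closed-form boundary — independent of the polygon-based pipeline
under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
from scipy.stats import truncnorm
from shapely.geometry import Point, Polygon

from .classify import classify_value
from .errors import ParameterError
from .planimetry import SliceGeometry

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "generate_stack",
    "generate_delta_T",
    "boundary_radius_exact",
    "notch_depth",
]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic ablation stack.

    Lengths in mm, flows in ml/min. ``notch_depth_max`` (kappa0) is the
    saturated fractional radial loss at the vessel azimuth;
    ``flow_steepness`` is the slope of the logistic flow response in
    log-flow. ``size_jitter_frac`` perturbs both ellipsoid semi-axes by a
    per-stack Gaussian factor, emulating the replicate-to-replicate spread
    of real ablations; ``boundary_noise_sd_mm`` is i.i.d. radial vertex
    noise emulating contour-tracing error.
    """

    semi_axis_a_mm: float = 18.0
    semi_axis_b_mm: float = 16.0
    av_distance_mm: float = 5.0
    flow_ml_min: float = 0.0
    notch_depth_max: float = 0.73
    notch_azimuth_sigma_rad: float = 0.5
    border_peak_mm: float = 7.5
    border_sigma_mm: float = 3.0
    flow_midpoint_base_ml_min: float = 20.0
    flow_midpoint_decay_mm: float = 4.0
    flow_steepness: float = 2.0
    rz_margin_mm: float = 3.0
    boundary_noise_sd_mm: float = 0.2
    size_jitter_frac: float = 0.02
    polygon_vertices_per_slice: int = 256
    slice_spacing_mm: float = 2.0
    slice_span_mm: float = 20.0
    min_slice_radius_mm: float = 6.0
    vessel_outer_radius_mm: float = 2.5
    vessel_inner_radius_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.notch_depth_max < 1.0):
            raise ParameterError("notch_depth_max must lie in [0, 1)")
        for name in (
            "semi_axis_a_mm",
            "semi_axis_b_mm",
            "av_distance_mm",
            "notch_azimuth_sigma_rad",
            "border_peak_mm",
            "border_sigma_mm",
            "flow_midpoint_base_ml_min",
            "flow_midpoint_decay_mm",
            "flow_steepness",
            "slice_spacing_mm",
            "slice_span_mm",
            "vessel_outer_radius_mm",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.flow_ml_min < 0:
            raise ParameterError("flow_ml_min must be >= 0")
        if self.boundary_noise_sd_mm < 0 or self.size_jitter_frac < 0:
            raise ParameterError("noise parameters must be >= 0")
        if self.rz_margin_mm < 0:
            raise ParameterError("rz_margin_mm must be >= 0")
        if self.min_slice_radius_mm < 0:
            raise ParameterError("min_slice_radius_mm must be >= 0")
        if self.polygon_vertices_per_slice < 16:
            raise ParameterError("polygon_vertices_per_slice must be >= 16")

    def with_(self, **kw) -> "PhantomParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown phantom keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PhantomTruth:
    """Analytic ground truth for one generated stack (noise-free boundary).

    Volumes refer to the vessel-containing half of the realized (jittered)
    ellipsoid and are obtained by numerical integration at much finer
    axial/angular resolution than the 2 mm / per-vertex sampling of the
    pipeline under test.
    """

    half_ablation_volume_ml: float
    cooling_volume_ml: float
    slice_offsets_mm: list[float]
    slice_cooling_areas_mm2: list[float]
    slice_cooling_types: list[int]
    realized_semi_axis_a_mm: float
    realized_semi_axis_b_mm: float


def notch_depth(params: PhantomParams, z: float | np.ndarray) -> float | np.ndarray:
    """Notch depth kappa(z) in [0, 1) for slices at axial offset z."""
    rho = np.hypot(params.av_distance_mm, z)
    border = np.exp(-((rho - params.border_peak_mm) ** 2) / (2.0 * params.border_sigma_mm**2))
    q = params.flow_ml_min
    if q <= 0:
        logistic = np.zeros_like(np.asarray(rho, dtype=float))
    else:
        q50 = params.flow_midpoint_base_ml_min * np.exp(-rho / params.flow_midpoint_decay_mm)
        logistic = 1.0 / (1.0 + (q50 / q) ** params.flow_steepness)
    out = params.notch_depth_max * logistic * border
    return float(out) if np.isscalar(z) else out


def boundary_radius_exact(
    params: PhantomParams,
    z: float | np.ndarray,
    theta: float | np.ndarray,
    a_mm: Optional[float] = None,
    b_mm: Optional[float] = None,
) -> np.ndarray:
    """Closed-form noise-free boundary radius r(theta, z) about the antenna.

    ``a_mm``/``b_mm`` override the nominal semi-axes (used for jittered
    stacks, where truth refers to the realized axes).
    """
    a = params.semi_axis_a_mm if a_mm is None else a_mm
    b = params.semi_axis_b_mm if b_mm is None else b_mm
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    r0 = b * np.sqrt(np.clip(1.0 - (z / a) ** 2, 0.0, None))
    dtheta = np.mod(theta + math.pi, 2.0 * math.pi) - math.pi  # vessel azimuth = 0
    notch = np.exp(-(dtheta**2) / (2.0 * params.notch_azimuth_sigma_rad**2))
    kappa = notch_depth(params, z)
    return r0 * (1.0 - np.asarray(kappa) * notch)


def _slice_offsets(params: PhantomParams, a_mm: float, b_mm: float) -> list[float]:
    """Section offsets: multiples of the spacing where the cross section is recordable.

    Slices are recorded only while the uncooled cross-section radius
    exceeds ``min_slice_radius_mm``, within |z| < a and the sectioning
    span: end-cap sections smaller than roughly the vessel diameter
    cannot be traced and graded reliably, and their landmarks (antenna,
    vessel, contour) collapse into tracing noise.
    """
    h = params.slice_spacing_mm
    kmax = int(math.floor(min(params.slice_span_mm, math.nextafter(a_mm, 0.0)) / h))
    out = []
    for k in range(-kmax, kmax + 1):
        z = k * h
        r0 = b_mm * math.sqrt(max(0.0, 1.0 - (z / a_mm) ** 2))
        if r0 >= params.min_slice_radius_mm:
            out.append(float(z))
    return out


def _truth(
    params: PhantomParams,
    a_mm: float,
    b_mm: float,
    offsets: list[float],
    tau_minor: float,
    tau_moderate: float,
    axial_step_mm: float,
    n_theta: int,
) -> PhantomTruth:
    """High-resolution integration of the closed-form boundary (the oracle)."""
    zmax = math.nextafter(a_mm, 0.0)
    n_z = max(3, int(math.ceil(2 * zmax / axial_step_mm)) + 1)
    zg = np.linspace(-zmax, zmax, n_z)
    th_half = np.linspace(-math.pi / 2, math.pi / 2, n_theta)  # vessel half = sector |theta|<=pi/2
    th_full = np.linspace(-math.pi, math.pi, 2 * n_theta)
    r_half = boundary_radius_exact(params, zg[:, None], th_half[None, :], a_mm, b_mm)
    half_area = 0.5 * np.trapezoid(r_half**2, th_half, axis=1)
    r_full = boundary_radius_exact(params, zg[:, None], th_full[None, :], a_mm, b_mm)
    r_max = np.max(r_full, axis=1)
    cool_area = 0.5 * math.pi * r_max**2 - half_area
    half_volume = float(np.trapezoid(half_area, zg) / 1000.0)
    cooling_volume = float(np.trapezoid(cool_area, zg) / 1000.0)

    # per-slice truth at the actual section offsets
    slice_areas: list[float] = []
    slice_types: list[int] = []
    th_dense = np.linspace(-math.pi, math.pi, 4096, endpoint=False)
    for z in offsets:
        r_h = boundary_radius_exact(params, z, th_half, a_mm, b_mm)
        area_h = float(0.5 * np.trapezoid(r_h**2, th_half))
        r_f = boundary_radius_exact(params, z, th_dense, a_mm, b_mm)
        rmax = float(np.max(r_f))
        slice_areas.append(max(0.0, 0.5 * math.pi * rmax**2 - area_h))
        r_at_vessel = float(boundary_radius_exact(params, z, 0.0, a_mm, b_mm))
        iota = min(1.0, max(0.0, 1.0 - r_at_vessel / rmax)) if rmax > 0 else 0.0
        ring = np.column_stack([r_f * np.cos(th_dense), r_f * np.sin(th_dense)])
        disc = Point(params.av_distance_mm, 0.0).buffer(params.vessel_outer_radius_mm, quad_segs=128)
        f = Polygon(ring).intersection(disc).area / disc.area
        f = min(1.0, max(0.0, f))
        slice_types.append(int(classify_value(iota, f, tau_minor, tau_moderate)))
    return PhantomTruth(
        half_ablation_volume_ml=half_volume,
        cooling_volume_ml=cooling_volume,
        slice_offsets_mm=list(offsets),
        slice_cooling_areas_mm2=slice_areas,
        slice_cooling_types=slice_types,
        realized_semi_axis_a_mm=a_mm,
        realized_semi_axis_b_mm=b_mm,
    )


def generate_stack(
    params: PhantomParams,
    with_truth: bool = True,
    tau_minor: float = 0.05,
    tau_moderate: float = 0.20,
    truth_axial_step_mm: float = 0.1,
    truth_n_theta: int = 2048,
) -> tuple[list[SliceGeometry], Optional[PhantomTruth]]:
    """Generate one slice stack (and, optionally, its analytic ground truth).

    Slices are placed at offsets z in {0, +-h, ...} with |z| < a (clipped
    to ``slice_span_mm``). Polygons are star-shaped about the antenna
    point at the in-plane origin; the vessel lies at (d, 0). The red zone
    is the white zone dilated by ``rz_margin_mm``.

    Randomness (axis jitter, then per-slice radial vertex noise in
    ascending-offset order) is driven entirely by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    jit_a, jit_b = rng.normal(0.0, params.size_jitter_frac, size=2) if params.size_jitter_frac > 0 else (0.0, 0.0)
    a_mm = params.semi_axis_a_mm * max(0.5, 1.0 + jit_a)
    b_mm = params.semi_axis_b_mm * max(0.5, 1.0 + jit_b)
    offsets = _slice_offsets(params, a_mm, b_mm)
    n = params.polygon_vertices_per_slice
    thetas = -math.pi + 2.0 * math.pi * np.arange(n) / n  # includes theta = 0 for even n
    slices: list[SliceGeometry] = []
    for z in offsets:
        r = boundary_radius_exact(params, z, thetas, a_mm, b_mm)
        if params.boundary_noise_sd_mm > 0:
            r = r + rng.normal(0.0, params.boundary_noise_sd_mm, size=n)
        r = np.maximum(r, 0.05)  # keep the contour star-shaped and positive
        wz = np.column_stack([r * np.cos(thetas), r * np.sin(thetas)])
        rz = None
        if params.rz_margin_mm > 0:
            dil = Polygon(wz).buffer(params.rz_margin_mm, quad_segs=32)
            rz = np.asarray(dil.exterior.coords, dtype=float)[:-1]
        slices.append(
            SliceGeometry(
                offset_mm=float(z),
                wz_polygon=wz,
                rz_polygon=rz,
                antenna_point=np.zeros(2),
                vessel_centre=np.array([params.av_distance_mm, 0.0]),
                vessel_outer_radius_mm=params.vessel_outer_radius_mm,
                vessel_inner_radius_mm=params.vessel_inner_radius_mm,
                scale_mm_per_unit=1.0,
            )
        )
    truth = None
    if with_truth:
        truth = _truth(
            params, a_mm, b_mm, offsets, tau_minor, tau_moderate, truth_axial_step_mm, truth_n_theta
        )
    return slices, truth


def generate_delta_T(
    flow_ml_min: float,
    n: int,
    seed: int,
    mean_K: float = 0.6,
    sd_K: float = 0.1,
) -> np.ndarray:
    """Draw coolant temperature rises (K) for one perfused test series.

    Temperature rises were only measured at flow rates >= 100 ml/min; the
    default distribution is a normal with mean 0.6 K (the recorded overall
    median) and sd 0.1 K, truncated at 0.
    """
    if flow_ml_min < 100:
        raise ParameterError("generate_delta_T: defined only for flow rates >= 100 ml/min")
    if n < 1:
        raise ParameterError("generate_delta_T: n must be >= 1")
    if sd_K < 0:
        raise ParameterError("generate_delta_T: sd must be >= 0")
    if sd_K == 0:
        return np.full(n, float(mean_K))
    rng = np.random.default_rng(seed)
    a = (0.0 - mean_K) / sd_K
    return truncnorm.rvs(a, np.inf, loc=mean_K, scale=sd_K, size=n, random_state=rng)
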