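"""Per-slice polygon planimetry against closed forms and Monte-Carlo oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mwacool import (
    GeometryError,
    ParameterError,
    PhantomParams,
    boundary_radius_at_azimuth,
    generate_stack,
    max_radius,
    polygon_area,
    vessel_enclosure_fraction,
    vessel_half,
)
from conftest import regular_polygon

ORIGIN = np.zeros(2)


class TestPolygonArea:
    @pytest.mark.parametrize(
        "poly, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (4, 0), (0, 3)], 6.0),
            ([(0, 0), (0, 3), (4, 0)], 6.0),  # clockwise storage: same area
        ],
    )
    def test_shoelace_examples(self, poly, expected):
        assert polygon_area(np.array(poly, dtype=float)) == pytest.approx(expected)

    def test_regular_64gon_closed_form(self):
        n, R = 64, 10.0
        expected = 0.5 * n * R * R * math.sin(2 * math.pi / n)  # 313.65..., -> pi R^2
        assert polygon_area(regular_polygon(n, R)) == pytest.approx(expected, rel=1e-12)

    def test_rejects_degenerate_and_self_intersecting(self):
        with pytest.raises(GeometryError):
            polygon_area(np.array([(0.0, 0.0), (1.0, 1.0)]))
        bowtie = np.array([(0, 0), (1, 1), (1, 0), (0, 1)], dtype=float)
        with pytest.raises(GeometryError):
            polygon_area(bowtie)


class TestMaxRadius:
    def test_square_diagonal(self):
        square = np.array([(1, 1), (-1, 1), (-1, -1), (1, -1)], dtype=float)
        assert max_radius(square, ORIGIN) == pytest.approx(math.sqrt(2))

    def test_centred_and_offset_origin_match_vertex_brute_force(self):
        poly = regular_polygon(64, 10.0)
        assert max_radius(poly, ORIGIN) == pytest.approx(10.0)
        origin = np.array([3.0, 0.0])
        brute = max(math.hypot(x - 3.0, y) for x, y in poly)
        assert max_radius(poly, origin) == pytest.approx(brute)
        assert brute == pytest.approx(13.0)

    def test_origin_outside_is_an_error(self):
        with pytest.raises(GeometryError):
            max_radius(regular_polygon(16, 1.0), np.array([5.0, 0.0]))


class TestVesselHalf:
    def test_circle_halves_to_half_disc(self):
        poly = regular_polygon(4096, 10.0)
        half = vessel_half(poly, ORIGIN, np.array([5.0, 0.0]))
        assert polygon_area(half) == pytest.approx(50 * math.pi, rel=1e-4)

    def test_polygon_entirely_on_vessel_side_unchanged_in_area(self):
        poly = regular_polygon(32, 1.0, centre=(5.0, 0.0))
        half = vessel_half(poly, ORIGIN, np.array([5.0, 0.0]))
        assert polygon_area(half) == pytest.approx(polygon_area(poly), rel=1e-12)

    def test_half_areas_sum_to_whole(self):
        """Clipping to the vessel side and the opposite side partitions the area."""
        params = PhantomParams(
            av_distance_mm=5.0, flow_ml_min=100.0, boundary_noise_sd_mm=0.0,
            size_jitter_frac=0.0, seed=3,
        )
        slices, _ = generate_stack(params, with_truth=False)
        s = slices[len(slices) // 2]
        total = polygon_area(s.wz_polygon)
        a = polygon_area(vessel_half(s.wz_polygon, s.antenna_point, s.vessel_centre))
        b = polygon_area(vessel_half(s.wz_polygon, s.antenna_point, -s.vessel_centre))
        assert a + b == pytest.approx(total, rel=1e-6)

    def test_notched_slice_matches_monte_carlo(self):
        """Clipped area agrees with a 10^6-point point-in-half-plane Monte Carlo."""
        params = PhantomParams(
            av_distance_mm=5.0, flow_ml_min=500.0, notch_depth_max=0.5,
            boundary_noise_sd_mm=0.0, size_jitter_frac=0.0, seed=11,
        )
        slices, _ = generate_stack(params, with_truth=False)
        s = slices[len(slices) // 2]
        half = vessel_half(s.wz_polygon, s.antenna_point, s.vessel_centre)
        area = polygon_area(half)
        rng = np.random.default_rng(99)
        lo = s.wz_polygon.min(axis=0)
        hi = s.wz_polygon.max(axis=0)
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        import shapely

        inside = shapely.contains_xy(shapely.polygons(s.wz_polygon), pts[:, 0], pts[:, 1])
        mc = np.mean(inside & (pts[:, 0] >= 0)) * np.prod(hi - lo)
        assert area == pytest.approx(mc, rel=5e-3)

    def test_degenerate_clip_is_an_error(self):
        poly = regular_polygon(32, 1.0, centre=(5.0, 0.0))
        # vessel on the far side: nothing of the polygon lies in x <= 0
        with pytest.raises(GeometryError):
            vessel_half(poly, ORIGIN, np.array([-5.0, 0.0]))


class TestBoundaryRadiusAtAzimuth:
    def test_circle_and_square(self):
        assert boundary_radius_at_azimuth(regular_polygon(512, 10.0), ORIGIN, 1.2345) == pytest.approx(10.0, rel=1e-4)
        square = np.array([(1, 1), (-1, 1), (-1, -1), (1, -1)], dtype=float)
        assert boundary_radius_at_azimuth(square, ORIGIN, 0.0) == pytest.approx(1.0)

    def test_phantom_notch_depth_recovered(self):
        """At the vessel azimuth the boundary sits at (1 - kappa) * r0."""
        kappa0 = 0.3
        params = PhantomParams(
            av_distance_mm=7.5, flow_ml_min=1e9, notch_depth_max=kappa0,
            border_sigma_mm=1e6, boundary_noise_sd_mm=0.0, size_jitter_frac=0.0,
            polygon_vertices_per_slice=512, seed=5,
        )
        # border factor ~= 1 at z = 0 (rho = rho* = 7.5), L ~= 1 at huge flow
        slices, _ = generate_stack(params, with_truth=False)
        s = [x for x in slices if x.offset_mm == 0][0]
        r0 = 16.0
        r = boundary_radius_at_azimuth(s.wz_polygon, s.antenna_point, 0.0)
        assert r == pytest.approx((1 - kappa0) * r0, rel=1e-3)

    def test_no_intersection_raises_with_azimuth(self):
        poly = regular_polygon(16, 1.0)
        with pytest.raises(GeometryError, match="origin"):
            boundary_radius_at_azimuth(poly, np.array([10.0, 0.0]), 0.0)

    def test_folded_contour_warns_and_returns_nearest(self):
        # a spiral-like notch making the ray at theta=0 cross three times
        poly = np.array(
            [(2, -2), (2, 2), (-2, 2), (-2, -2), (0.5, -2), (0.5, 0.5), (1, 0.5), (1, -2)],
            dtype=float,
        )
        origin = np.array([0.0, -1.0])
        with pytest.warns(UserWarning, match="not star-shaped"):
            r = boundary_radius_at_azimuth(poly, origin, 0.0)
        assert r == pytest.approx(0.5)


class TestEnclosureFraction:
    def test_inside_outside_and_edge(self):
        rect = np.array([(-100, -100), (100, -100), (100, 100), (-100, 100)], dtype=float)
        assert vessel_enclosure_fraction(rect, np.array([0.0, 0.0]), 2.5) == pytest.approx(1.0)
        assert vessel_enclosure_fraction(rect, np.array([500.0, 0.0]), 2.5) == pytest.approx(0.0)
        # disc centred on a long straight edge: exactly half covered
        assert vessel_enclosure_fraction(rect, np.array([100.0, 0.0]), 2.5) == pytest.approx(0.5, abs=1e-3)

    def test_zero_radius_is_parameter_error(self):
        rect = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)
        with pytest.raises(ParameterError):
            vessel_enclosure_fraction(rect, ORIGIN, 0.0)


@given(
    radii=st.lists(st.floats(1.0, 20.0), min_size=16, max_size=48),
    theta=st.floats(-math.pi, math.pi),
)
def test_max_radius_dominates_azimuthal_radius(radii, theta):
    """r_max >= r(theta) for any azimuth of a star-shaped polygon."""
    n = len(radii)
    th = 2 * math.pi * np.arange(n) / n
    r = np.asarray(radii)
    poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hypothesis may build slightly folded shapes
        rmax = max_radius(poly, ORIGIN)
        raz = boundary_radius_at_azimuth(poly, ORIGIN, theta)
    assert raz <= rmax + 1e-9
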