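"""Frustum volumetry, idealized ablation, cooling areas/portions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mwacool import (
    DataError,
    MeasurementError,
    ParameterError,
    PhantomParams,
    cooling_area,
    cooling_portion,
    frustum_volume,
    idealized_half_area,
    round_half_up,
    stack_report,
)
from mwacool.planimetry import SliceMeasurement


def _measurement(offset=0.0, half=50.0, ideal=60.0):
    return SliceMeasurement(
        offset_mm=offset, wz_area_mm2=2 * half, r_max_mm=math.sqrt(2 * ideal / math.pi),
        half_area_mm2=half, idealized_half_area_mm2=ideal, cooling_area_mm2=0.0,
        indentation_ratio=0.0, enclosure_fraction=1.0,
    )


class TestFrustumVolume:
    def test_constant_profile(self):
        assert frustum_volume([50.0] * 11, 2.0) == pytest.approx(1.0)

    def test_two_slices(self):
        assert frustum_volume([100.0, 0.0], 2.0) == pytest.approx(0.1)

    def test_sampled_cone_matches_hand_trapezoid(self):
        # cone R = 10 mm, h = 20 mm, areas pi (10 - z/2)^2 every 2 mm
        z = np.arange(0, 21, 2.0)
        areas = math.pi * (10 - z / 2) ** 2
        v = frustum_volume(areas, 2.0)
        assert v == pytest.approx(670 * math.pi / 1000.0, rel=1e-12)  # 2.1049 ml
        # analytic cone volume (1/3) pi R^2 h = 2.094 ml: trapezoid overestimates slightly
        assert v == pytest.approx(math.pi * 100 * 20 / 3 / 1000.0, rel=0.01)

    def test_half_ellipsoid_convergence_is_second_order(self):
        a, b = 18.0, 16.0
        exact = 0.5 * (4.0 / 3.0) * math.pi * a * b * b / 1000.0

        def err(h):
            z = np.arange(-a, a + h / 2, h)
            areas = 0.5 * math.pi * b * b * np.clip(1 - (z / a) ** 2, 0, None)
            return frustum_volume(areas, h) - exact

        e2, e1 = err(2.0), err(1.0)
        assert abs(e2) / exact <= 0.02
        assert 1.7 <= math.log2(abs(e2 / e1)) <= 2.3

    def test_errors(self):
        with pytest.raises(MeasurementError):
            frustum_volume([50.0], 2.0)
        with pytest.raises(DataError):
            frustum_volume([50.0, -1.0], 2.0)
        with pytest.raises(ParameterError):
            frustum_volume([50.0, 50.0], 0.0)

    @given(
        areas=st.lists(st.floats(0.0, 500.0), min_size=2, max_size=20),
        spacing=st.floats(0.5, 4.0),
        scale=st.floats(0.2, 5.0),
    )
    def test_scale_equivariance(self, areas, spacing, scale):
        """Scaling lengths by s scales areas by s^2 and volumes by s^3."""
        v1 = frustum_volume(np.asarray(areas) * scale * scale, spacing * scale)
        v0 = frustum_volume(areas, spacing)
        assert v1 == pytest.approx(v0 * scale**3, rel=1e-9, abs=1e-12)


class TestIdealizedHalfArea:
    @pytest.mark.parametrize(
        "r, expected",
        [(10.0, 157.07963), (0.0, 0.0), (math.sqrt(2 / math.pi), 1.0)],
    )
    def test_half_disc(self, r, expected):
        assert idealized_half_area(r) == pytest.approx(expected, rel=1e-6)

    def test_negative_is_data_error(self):
        with pytest.raises(DataError):
            idealized_half_area(-1.0)


class TestCoolingArea:
    def test_perfect_half_disc_has_zero_cooling(self):
        m = _measurement(half=157.0796, ideal=157.0796)
        assert cooling_area(m) == 0.0

    def test_notch_area_is_additive(self):
        ideal = idealized_half_area(10.0)
        m = _measurement(half=ideal - 20.0, ideal=ideal)
        assert cooling_area(m) == pytest.approx(20.0)

    def test_missing_fields_raise(self):
        m = _measurement()
        m.half_area_mm2 = float("nan")
        with pytest.raises(DataError):
            cooling_area(m)

    def test_phantom_notch_matches_analytic_integral(self):
        """Measured cooling area vs the generator's closed-form notch integral.

        For r(theta) = r0 (1 - k g(theta)), the half cooling area is
        0.5 * int_{-pi/2}^{pi/2} r0^2 [1 - (1 - k g)^2] dtheta.
        """
        kappa0, sigma = 0.3, 0.5
        params = PhantomParams(
            av_distance_mm=7.5, flow_ml_min=1e9, notch_depth_max=kappa0,
            notch_azimuth_sigma_rad=sigma, border_sigma_mm=1e6,
            boundary_noise_sd_mm=0.0, size_jitter_frac=0.0,
            polygon_vertices_per_slice=512, seed=2,
        )
        from mwacool import generate_stack, measure_slice

        slices, _ = generate_stack(params, with_truth=False)
        s = [x for x in slices if x.offset_mm == 0][0]
        m = measure_slice(s)
        th = np.linspace(-math.pi / 2, math.pi / 2, 200001)
        g = np.exp(-(th**2) / (2 * sigma**2))
        r0 = 16.0
        analytic = 0.5 * np.trapezoid(r0**2 * (1 - (1 - kappa0 * g) ** 2), th)
        assert m.cooling_area_mm2 == pytest.approx(analytic, rel=0.01)


class TestStackReport:
    def test_uncooled_circles_have_no_cooling(self, measured_stack_factory, noise_free_params):
        # inscribed-polygon area deficit (~1e-4 relative at 256 vertices)
        # leaves a ~0.001 ml residual against the r_max half-disc
        ms, report, truth = measured_stack_factory(noise_free_params.with_(flow_ml_min=0.0))
        assert report.cooling_volume_ml == pytest.approx(0.0, abs=2e-3)
        assert report.cooling_portion_pct == pytest.approx(0.0, abs=0.05)
        assert truth.cooling_volume_ml == pytest.approx(0.0, abs=1e-9)

    def test_cooling_volume_recovers_truth(self, measured_stack_factory, noise_free_params):
        params = noise_free_params.with_(
            notch_depth_max=0.5, flow_ml_min=100.0, polygon_vertices_per_slice=512
        )
        _, report, truth = measured_stack_factory(params)
        assert report.cooling_volume_ml == pytest.approx(truth.cooling_volume_ml, rel=0.05)

    def test_additivity_is_exact(self, measured_stack_factory):
        params = PhantomParams(flow_ml_min=100.0, seed=13)
        _, report, _ = measured_stack_factory(params)
        assert report.idealized_volume_ml == report.ablation_volume_ml + report.cooling_volume_ml

    def test_cooling_volume_monotone_in_flow(self, measured_stack_factory, noise_free_params):
        vols = []
        for q in (0.0, 1.0, 2.0, 5.0, 10.0, 100.0, 500.0):
            _, report, truth = measured_stack_factory(noise_free_params.with_(flow_ml_min=q))
            vols.append((report.cooling_volume_ml, truth.cooling_volume_ml))
        pipe, true = zip(*vols)
        assert all(b >= a - 1e-9 for a, b in zip(pipe, pipe[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(true, true[1:]))

    def test_non_uniform_spacing_rejected(self):
        ms = [_measurement(offset=z) for z in (0.0, 2.0, 4.5)]
        with pytest.raises(DataError, match="spacing"):
            stack_report(ms, 2.0)


class TestCoolingPortion:
    @pytest.mark.parametrize(
        "cool, abl, pct",
        [(1.8, 5.4, 33), (0.6, 7.2, 8), (0.8, 7.4, 11), (1.7, 4.4, 39), (1.6, 6.9, 23), (0.0, 5.0, 0)],
    )
    def test_tabulated_integer_percentages(self, cool, abl, pct):
        assert round_half_up(cooling_portion(cool, abl)) == pct

    def test_zero_ablation_volume_is_undefined(self):
        with pytest.raises(DataError):
            cooling_portion(1.0, 0.0)
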