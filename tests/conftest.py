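"""Shared fixtures and hypothesis configuration."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mwacool import PhantomParams, classify_slice, generate_stack, measure_slice, stack_report

settings.register_profile(
    "mwacool",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mwacool")


@pytest.fixture(scope="session")
def noise_free_params() -> PhantomParams:
    """Deterministic phantom: no vertex noise, no replicate size jitter."""
    return PhantomParams(boundary_noise_sd_mm=0.0, size_jitter_frac=0.0, seed=7)


def regular_polygon(n: int, radius: float, centre=(0.0, 0.0)) -> np.ndarray:
    th = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([centre[0] + radius * np.cos(th), centre[1] + radius * np.sin(th)])


@pytest.fixture(scope="session")
def measured_stack_factory():
    """Generate -> measure -> classify one phantom stack; returns (measurements, report, truth)."""

    def factory(params: PhantomParams, spacing: float = 2.0, with_truth: bool = True,
                tau_minor: float = 0.05, tau_moderate: float = 0.20):
        slices, truth = generate_stack(params, with_truth=with_truth)
        ms = []
        for s in slices:
            m = measure_slice(s)
            m.av_distance_mm = params.av_distance_mm
            m.flow_ml_min = params.flow_ml_min
            classify_slice(m, tau_minor, tau_moderate)
            ms.append(m)
        report = stack_report(ms, spacing, av_distance_mm=params.av_distance_mm,
                              flow_ml_min=params.flow_ml_min)
        return ms, report, truth

    return factory
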