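"""Factorial study design: antenna–vessel distances x coolant flow rates x replicates.

The default design is the full ex vivo protocol this package analyses:
three antenna–vessel (A–V) distances (2.5, 5.0, 10.0 mm), seven coolant
flow rates (0–500 ml/min) and six replicates per cell, ablated at 100 W
for 5 min and sectioned every 2 mm, with a nominal uncooled ablation of
3.6 x 3.2 cm (length x width). All fields can be overridden via JSON
config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigurationError

__all__ = ["StudyDesign", "RunSpec", "enumerate_runs"]


@dataclass(frozen=True)
class StudyDesign:
    """The factorial experiment configuration.

    Parameters
    ----------
    av_distances_mm
        In-plane antenna-to-vessel spacings (mm); all > 0.
    flow_rates_ml_min
        Coolant flow rates (ml/min); >= 0 and strictly increasing.
    replicates
        Ablations per (distance, flow) cell; >= 1.
    power_W, duration_s
        Generator power and ablation time.
    slice_spacing_mm
        Serial-section interval along the antenna axis.
    expected_ablation_mm
        Nominal uncooled ablation (length, width) in mm.
    """

    av_distances_mm: tuple[float, ...] = (2.5, 5.0, 10.0)
    flow_rates_ml_min: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, 100.0, 500.0)
    replicates: int = 6
    power_W: float = 100.0
    duration_s: float = 300.0
    slice_spacing_mm: float = 2.0
    expected_ablation_mm: tuple[float, float] = (36.0, 32.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "av_distances_mm", tuple(float(d) for d in self.av_distances_mm))
        object.__setattr__(self, "flow_rates_ml_min", tuple(float(q) for q in self.flow_rates_ml_min))
        object.__setattr__(self, "expected_ablation_mm", tuple(float(v) for v in self.expected_ablation_mm))
        if not self.av_distances_mm or any(d <= 0 for d in self.av_distances_mm):
            raise ConfigurationError("av_distances_mm: all distances must be > 0")
        if not self.flow_rates_ml_min or any(q < 0 for q in self.flow_rates_ml_min):
            raise ConfigurationError("flow_rates_ml_min: flow rates must be >= 0")
        if any(b <= a for a, b in zip(self.flow_rates_ml_min, self.flow_rates_ml_min[1:])):
            raise ConfigurationError("flow_rates_ml_min: flow rates must be strictly increasing")
        if int(self.replicates) != self.replicates or self.replicates < 1:
            raise ConfigurationError("replicates: must be an integer >= 1")
        if self.power_W <= 0:
            raise ConfigurationError("power_W: must be > 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s: must be > 0")
        if self.slice_spacing_mm <= 0:
            raise ConfigurationError("slice_spacing_mm: must be > 0")

    @property
    def n_runs(self) -> int:
        return len(self.av_distances_mm) * len(self.flow_rates_ml_min) * self.replicates

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown design keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyDesign":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class RunSpec:
    """One planned ablation run."""

    run_id: str
    av_distance_mm: float
    flow_ml_min: float
    replicate: int


def enumerate_runs(design: StudyDesign) -> list[RunSpec]:
    """Enumerate all planned runs in lexicographic (distance, flow, replicate) order.

    The default design yields 3 x 7 x 6 = 126 runs. Enumeration order is
    deterministic and stable across calls.
    """
    runs: list[RunSpec] = []
    for d in sorted(design.av_distances_mm):
        for q in design.flow_rates_ml_min:  # invariant: already strictly increasing
            for r in range(1, design.replicates + 1):
                runs.append(
                    RunSpec(
                        run_id=f"d{d:g}_q{q:g}_r{r}",
                        av_distance_mm=d,
                        flow_ml_min=q,
                        replicate=r,
                    )
                )
    return runs
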