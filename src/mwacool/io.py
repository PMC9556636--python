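"""Slice-table and report file formats.

The canonical geometry exchange format is a flat CSV ("slice table"):
one row per (run, slice offset, zone), the contour stored as a JSON array
of [x, y] millimetre pairs. Coordinates are already calibrated;
``scale_mm_per_unit`` is retained for provenance only. Exactly one WZ row
per (run, offset) is required; RZ rows are optional.

Report writers emit deterministic column order, floats at 6 significant
digits, and (for stack reports) the integer cooling portion used in
tabulation alongside the full-precision value.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import LoadError, ParameterError
from .planimetry import SliceGeometry, SliceMeasurement
from .volumetry import StackReport, round_half_up

__all__ = [
    "RunRecord",
    "SLICE_TABLE_COLUMNS",
    "write_slice_table",
    "read_slice_table",
    "write_reports",
    "write_measurements",
    "read_measurements",
    "write_table",
]

SLICE_TABLE_COLUMNS = [
    "run_id",
    "av_distance_mm",
    "flow_ml_min",
    "replicate",
    "offset_mm",
    "zone",
    "polygon",
    "antenna_x",
    "antenna_y",
    "vessel_x",
    "vessel_y",
    "vessel_outer_radius_mm",
    "scale_mm_per_unit",
]


@dataclasses.dataclass
class RunRecord:
    """One run's slices plus its factorial-cell metadata."""

    run_id: str
    av_distance_mm: float
    flow_ml_min: float
    replicate: int
    slices: list[SliceGeometry]


def write_slice_table(runs: Iterable[RunRecord], path: str | Path) -> None:
    """Serialize runs to the slice-table CSV (full float precision)."""
    rows = []
    for run in runs:
        for s in run.slices:
            zones = [("WZ", s.wz_polygon)]
            if s.rz_polygon is not None:
                zones.append(("RZ", s.rz_polygon))
            for zone, poly in zones:
                rows.append(
                    {
                        "run_id": run.run_id,
                        "av_distance_mm": run.av_distance_mm,
                        "flow_ml_min": run.flow_ml_min,
                        "replicate": run.replicate,
                        "offset_mm": s.offset_mm,
                        "zone": zone,
                        "polygon": json.dumps([[float(x), float(y)] for x, y in poly]),
                        "antenna_x": float(s.antenna_point[0]),
                        "antenna_y": float(s.antenna_point[1]),
                        "vessel_x": float(s.vessel_centre[0]),
                        "vessel_y": float(s.vessel_centre[1]),
                        "vessel_outer_radius_mm": s.vessel_outer_radius_mm,
                        "scale_mm_per_unit": s.scale_mm_per_unit,
                    }
                )
    pd.DataFrame(rows, columns=SLICE_TABLE_COLUMNS).to_csv(path, index=False)


def _parse_polygon(text: str, row: int) -> np.ndarray:
    try:
        data = json.loads(text)
    except (TypeError, json.JSONDecodeError) as exc:
        raise LoadError(f"row {row}: unparsable polygon JSON ({exc})") from exc
    try:
        arr = np.asarray(data, dtype=float)
    except ValueError as exc:
        raise LoadError(f"row {row}: polygon must be >= 3 finite [x, y] pairs") from exc
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
        raise LoadError(f"row {row}: polygon must be >= 3 finite [x, y] pairs")
    return arr


def read_slice_table(path: str | Path) -> list[RunRecord]:
    """Load and validate a slice-table CSV, grouped by run, sorted by offset."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise LoadError(f"cannot read slice table {path}: {exc}") from exc
    missing = [c for c in SLICE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"slice table {path} missing columns: {missing}")
    dup = df.duplicated(subset=["run_id", "offset_mm", "zone"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise LoadError(f"duplicate (run, offset, zone) rows at lines {rows[:10]}")
    runs: list[RunRecord] = []
    for run_id, g in df.groupby("run_id", sort=True):
        by_offset: dict[float, dict[str, tuple[int, pd.Series]]] = {}
        for idx, row in g.iterrows():
            by_offset.setdefault(float(row["offset_mm"]), {})[str(row["zone"])] = (int(idx), row)
        slices = []
        for offset in sorted(by_offset):
            zones = by_offset[offset]
            if "WZ" not in zones:
                raise LoadError(f"run {run_id}: missing WZ contour at offset {offset:g} mm")
            idx, row = zones["WZ"]
            wz = _parse_polygon(row["polygon"], idx + 2)
            rz = None
            if "RZ" in zones:
                ridx, rrow = zones["RZ"]
                rz = _parse_polygon(rrow["polygon"], ridx + 2)
            slices.append(
                SliceGeometry(
                    offset_mm=offset,
                    wz_polygon=wz,
                    rz_polygon=rz,
                    antenna_point=np.array([row["antenna_x"], row["antenna_y"]], dtype=float),
                    vessel_centre=np.array([row["vessel_x"], row["vessel_y"]], dtype=float),
                    vessel_outer_radius_mm=float(row["vessel_outer_radius_mm"]),
                    scale_mm_per_unit=float(row["scale_mm_per_unit"]),
                )
            )
        first = g.iloc[0]
        runs.append(
            RunRecord(
                run_id=str(run_id),
                av_distance_mm=float(first["av_distance_mm"]),
                flow_ml_min=float(first["flow_ml_min"]),
                replicate=int(first["replicate"]),
                slices=slices,
            )
        )
    return runs


def _sig6(v):
    if isinstance(v, float):
        if not math.isfinite(v):
            return v
        return float(f"{v:.6g}")
    return v


def write_reports(reports: Sequence[StackReport], path: str | Path, format: str = "csv") -> None:
    """Write stack reports as CSV or JSON with deterministic field order."""
    if format not in ("csv", "json"):
        raise ParameterError(f"write_reports: unknown format {format!r}")
    cols = [f.name for f in dataclasses.fields(StackReport)] + ["cooling_portion_int_pct"]
    rows = []
    for r in reports:
        d = dataclasses.asdict(r)
        d["cooling_portion_int_pct"] = (
            round_half_up(r.cooling_portion_pct) if r.cooling_portion_pct is not None else None
        )
        rows.append({k: _sig6(d[k]) for k in cols})
    if format == "csv":
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6g")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1, sort_keys=False)
            fh.write("\n")


MEASUREMENT_COLUMNS = [
    "run_id",
    "av_distance_mm",
    "flow_ml_min",
    "replicate",
    "offset_mm",
    "wz_area_mm2",
    "r_max_mm",
    "half_area_mm2",
    "idealized_half_area_mm2",
    "cooling_area_mm2",
    "indentation_ratio",
    "enclosure_fraction",
    "cooling_type",
]


def write_measurements(measurements: Sequence[SliceMeasurement], path: str | Path) -> None:
    rows = [{c: getattr(m, c if c != "replicate" else "replicate") for c in MEASUREMENT_COLUMNS} for m in measurements]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False, float_format="%.9g")


def read_measurements(path: str | Path) -> list[SliceMeasurement]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise LoadError(f"cannot read measurement table {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns and c != "cooling_type"]
    if missing:
        raise LoadError(f"measurement table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        ct = row.get("cooling_type")
        out.append(
            SliceMeasurement(
                offset_mm=float(row["offset_mm"]),
                wz_area_mm2=float(row["wz_area_mm2"]),
                r_max_mm=float(row["r_max_mm"]),
                half_area_mm2=float(row["half_area_mm2"]),
                idealized_half_area_mm2=float(row["idealized_half_area_mm2"]),
                cooling_area_mm2=float(row["cooling_area_mm2"]),
                indentation_ratio=float(row["indentation_ratio"]),
                enclosure_fraction=float(row["enclosure_fraction"]),
                cooling_type=None if ct is None or (isinstance(ct, float) and math.isnan(ct)) else int(ct),
                av_distance_mm=float(row["av_distance_mm"]),
                flow_ml_min=float(row["flow_ml_min"]),
                replicate=int(row["replicate"]),
                run_id=str(row["run_id"]),
            )
        )
    return out


def write_table(rows: Sequence[dict], path: str | Path, columns: Optional[list[str]] = None) -> None:
    """Generic deterministic CSV writer for profile / stats / energy tables."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, index=False, float_format="%.6g")
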