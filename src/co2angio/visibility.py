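"""Per-shot leak volume and sphere-equivalent visibility metrics.

A bolus ("one shot") of contrast transits the bleeding point for
``shot_volume / vessel_flow`` minutes; the leakage flow at the prevailing
intravascular pressure times this passage time is the volume deposited
outside the vessel per shot.  That volume, shaped into a sphere, projects
onto the fluoroscopic image as its great-circle disc — the disc diameter
and area are the visibility metrics, and CO2/iodine quotients of those
metrics quantify how much easier a gas leak is to spot.

Internal computation is full precision; :func:`round_sig` (3 significant
figures) is applied only when presenting values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .flow_model import FlowPressureModel, predict_flow
from .physics import projected_circle_area, sphere_equivalent_diameter

__all__ = [
    "ShotConfig",
    "VisibilityMetrics",
    "VisibilityRatio",
    "passage_time",
    "leak_volume_per_shot",
    "visibility_metrics",
    "visibility_ratio",
    "ratio_curve",
    "round_sig",
    "DEFAULT_PRESSURE_GRID",
]

#: Default grid for visibility/ratio tables, mmHg.
DEFAULT_PRESSURE_GRID = tuple(float(p) for p in range(10, 151, 10))

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ShotConfig:
    """One contrast injection into the target vessel.

    Defaults model a 20 mL bolus into a vessel carrying 200 mL/min
    (fasting superior mesenteric artery flow), giving a 0.1 min passage
    time past the bleeding point.
    """

    shot_volume_ml: float = 20.0
    vessel_flow_ml_min: float = 200.0

    def __post_init__(self) -> None:
        if not (self.shot_volume_ml > 0):
            raise ValueError("shot volume must be positive")
        if not (self.vessel_flow_ml_min > 0):
            raise ValueError("vessel flow must be positive")


@dataclass(frozen=True)
class VisibilityMetrics:
    """Leak volume and its sphere-equivalent projection at one pressure.

    The three geometric fields are mutually consistent by construction:
    ``diameter = (6 * 1000 * volume / pi)**(1/3)`` and
    ``area = pi * diameter**2 / 4``.
    """

    pressure_mmhg: float
    flow_ml_min: float
    leak_volume_ml: float
    diameter_mm: float
    area_mm2: float

    def __post_init__(self) -> None:
        for name in ("pressure_mmhg", "flow_ml_min", "leak_volume_ml", "diameter_mm", "area_mm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        d_expected = sphere_equivalent_diameter(self.leak_volume_ml)
        a_expected = projected_circle_area(self.diameter_mm)
        scale_d = max(d_expected, 1.0)
        scale_a = max(a_expected, 1.0)
        if abs(self.diameter_mm - d_expected) > _REL_TOL * scale_d:
            raise ValueError("diameter inconsistent with leak volume")
        if abs(self.area_mm2 - a_expected) > _REL_TOL * scale_a:
            raise ValueError("area inconsistent with diameter")

    @classmethod
    def from_leak_volume(
        cls,
        pressure_mmhg: float,
        leak_volume_ml: float,
        flow_ml_min: float | None = None,
        shot: "ShotConfig | None" = None,
    ) -> "VisibilityMetrics":
        """Build consistent metrics from a leaked volume.

        When ``flow_ml_min`` is omitted it is back-computed from the shot
        passage time (default shot if none given).
        """
        if flow_ml_min is None:
            flow_ml_min = leak_volume_ml / passage_time(shot or ShotConfig())
        d = sphere_equivalent_diameter(leak_volume_ml)
        return cls(pressure_mmhg, flow_ml_min, leak_volume_ml, d, projected_circle_area(d))


@dataclass(frozen=True)
class VisibilityRatio:
    """CO2/iodine quotients of the visibility metrics at one pressure."""

    pressure_mmhg: float
    flow_ratio: float
    volume_ratio: float
    diameter_ratio: float
    area_ratio: float


def passage_time(shot: ShotConfig) -> float:
    """Minutes for one shot to transit the bleeding point: V_shot / Q_vessel."""
    return shot.shot_volume_ml / shot.vessel_flow_ml_min


def leak_volume_per_shot(
    model: FlowPressureModel,
    pressure_mmhg: float,
    shot: ShotConfig,
) -> float:
    """Volume (mL) escaping the vessel during one shot at a given pressure."""
    return predict_flow(model, pressure_mmhg) * passage_time(shot)


def visibility_metrics(
    model: FlowPressureModel,
    pressure_mmhg: float,
    shot: ShotConfig,
) -> VisibilityMetrics:
    """Chain flow -> per-shot volume -> sphere diameter -> disc area."""
    flow = predict_flow(model, pressure_mmhg)
    volume = flow * passage_time(shot)
    diameter = sphere_equivalent_diameter(volume)
    return VisibilityMetrics(
        pressure_mmhg=pressure_mmhg,
        flow_ml_min=flow,
        leak_volume_ml=volume,
        diameter_mm=diameter,
        area_mm2=projected_circle_area(diameter),
    )


def visibility_ratio(co2: VisibilityMetrics, iodine: VisibilityMetrics) -> VisibilityRatio:
    """Element-wise CO2/iodine quotients; requires matching pressures.

    ``area_ratio == diameter_ratio**2`` holds exactly, and
    ``volume_ratio == flow_ratio`` whenever both metrics share a passage
    time.  Ratios are taken on unrounded values.
    """
    scale = max(abs(co2.pressure_mmhg), abs(iodine.pressure_mmhg), 1.0)
    if abs(co2.pressure_mmhg - iodine.pressure_mmhg) > _REL_TOL * scale:
        raise ValueError(
            f"pressure mismatch: {co2.pressure_mmhg} vs {iodine.pressure_mmhg} mmHg"
        )
    if min(iodine.flow_ml_min, iodine.leak_volume_ml, iodine.diameter_mm, iodine.area_mm2) <= 0:
        raise ValueError("iodine (denominator) metrics must be strictly positive")
    d_ratio = co2.diameter_mm / iodine.diameter_mm
    return VisibilityRatio(
        pressure_mmhg=co2.pressure_mmhg,
        flow_ratio=co2.flow_ml_min / iodine.flow_ml_min,
        volume_ratio=co2.leak_volume_ml / iodine.leak_volume_ml,
        diameter_ratio=d_ratio,
        area_ratio=d_ratio**2,
    )


def ratio_curve(
    model_co2: FlowPressureModel,
    model_iodine: FlowPressureModel,
    pressure_grid: Iterable[float],
    shot: ShotConfig,
) -> list[VisibilityRatio]:
    """CO2/iodine visibility ratios along a pressure grid.

    For power-law models with a smaller CO2 exponent the diameter ratio
    decreases with pressure: the gas advantage is largest where bleeding
    is hardest to see.
    """
    grid = [float(p) for p in pressure_grid]
    if not grid:
        raise ValueError("pressure grid must be non-empty")
    if any(p <= 0 for p in grid):
        raise ValueError("ratio grid pressures must be positive")
    return [
        visibility_ratio(
            visibility_metrics(model_co2, p, shot),
            visibility_metrics(model_iodine, p, shot),
        )
        for p in grid
    ]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
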