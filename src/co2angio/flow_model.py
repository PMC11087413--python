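"""Least-squares leakage-flow vs intravascular-pressure models.

Each (fluid, wound) condition yields a set of steady-state
(pressure, flow) points; this module fits either a power law
``Q = a * P**b`` (default — it covers both the laminar ``b ~ 1`` and the
orifice ``b ~ 0.5`` regimes) or a line through the origin ``Q = a * P``,
and carries the fit statistics a practitioner reports: Pearson r, its
two-sided p-value, and the coefficient of determination computed on the
original (non-log) scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SteadyStateMeasurement",
    "FlowPressureModel",
    "fit_flow_pressure",
    "predict_flow",
    "compare_conditions",
]

logger = logging.getLogger(__name__)

MODEL_FORMS = ("power_law", "linear_origin")


@dataclass(frozen=True)
class SteadyStateMeasurement:
    """One stabilization-plateau observation for a single condition.

    ``flow_ml_min`` is the extravascular (expansion-corrected) leakage
    flow; for liquids it coincides with the injected flow.
    """

    fluid: str
    wound: str
    pressure_mmhg: float
    flow_ml_min: float

    def __post_init__(self) -> None:
        if not (self.pressure_mmhg > 0):
            raise ValueError(f"pressure must be positive, got {self.pressure_mmhg}")
        if self.flow_ml_min < 0:
            raise ValueError(f"flow must be non-negative, got {self.flow_ml_min}")


@dataclass
class FlowPressureModel:
    """A fitted flow-pressure relation for one (fluid, wound) condition.

    ``coefficient_a`` is the conductance-like prefactor in
    mL/min/mmHg**b; ``exponent_b`` is 1.0 for the linear-through-origin
    form.  ``pearson_r``/``p_value`` are NaN when all flows are equal
    (the correlation is undefined), in which case ``r_squared`` is 0.
    """

    fluid: str
    wound: str
    form: str
    coefficient_a: float
    exponent_b: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int
    dropped_zero_flows: int = field(default=0)

    def __post_init__(self) -> None:
        if self.form not in MODEL_FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if not (self.coefficient_a > 0):
            raise ValueError("fitted coefficient must be positive")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.fluid, self.wound)

    def predict(self, pressure_mmhg: float) -> float:
        return predict_flow(self, pressure_mmhg)

    def to_dict(self) -> dict:
        def _json_float(x: float):
            return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x

        return {
            "fluid": self.fluid,
            "wound": self.wound,
            "form": self.form,
            "coefficient_a": self.coefficient_a,
            "exponent_b": self.exponent_b,
            "pearson_r": _json_float(self.pearson_r),
            "r_squared": self.r_squared,
            "p_value": _json_float(self.p_value),
            "n": self.n,
            "dropped_zero_flows": self.dropped_zero_flows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlowPressureModel":
        d = dict(d)
        for key in ("pearson_r", "p_value"):
            if d.get(key) is None:
                d[key] = float("nan")
        return cls(**d)


def _check_condition(measurements: Sequence[SteadyStateMeasurement]) -> tuple[str, str]:
    conditions = {(m.fluid, m.wound) for m in measurements}
    if len(conditions) != 1:
        raise ValueError(f"measurements span multiple conditions: {sorted(conditions)}")
    return conditions.pop()


def fit_flow_pressure(
    measurements: Sequence[SteadyStateMeasurement],
    form: str = "power_law",
) -> FlowPressureModel:
    """Least-squares fit of leakage flow against stabilization pressure.

    Power-law coefficients are estimated in log-log space (zero-flow
    points carry no information there and are dropped with a warning);
    the line through the origin has the closed-form estimate
    ``a = sum(P*Q) / sum(P**2)``.  R^2 is always evaluated on the
    original scale as ``1 - SS_res / SS_tot`` so the two forms are
    directly comparable.

    Raises
    ------
    ValueError
        For fewer than 3 points, mixed conditions, fewer than 2 distinct
        pressures, or an unknown form.
    """
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}; expected one of {MODEL_FORMS}")
    measurements = list(measurements)
    if len(measurements) < 3:
        raise ValueError(f"need at least 3 measurements, got {len(measurements)}")
    fluid, wound = _check_condition(measurements)

    pressure = np.array([m.pressure_mmhg for m in measurements], dtype=float)
    flow = np.array([m.flow_ml_min for m in measurements], dtype=float)
    if np.unique(pressure).size < 2:
        raise ValueError("degenerate data: all pressures identical")

    dropped = 0
    if form == "power_law":
        positive = flow > 0
        dropped = int(np.count_nonzero(~positive))
        if dropped:
            logger.warning(
                "%s/%s: dropping %d zero-flow point(s) for log-log fitting",
                fluid, wound, dropped,
            )
        p_fit, q_fit = pressure[positive], flow[positive]
        if p_fit.size < 3 or np.unique(p_fit).size < 2:
            raise ValueError("too few positive-flow points for a power-law fit")
        if np.ptp(q_fit) == 0 and np.ptp(np.log(p_fit)) > 0:
            # flat flows: slope 0, prefactor the common flow value
            a, b = float(q_fit[0]), 0.0
        else:
            slope, intercept, *_ = stats.linregress(np.log(p_fit), np.log(q_fit))
            a, b = float(np.exp(intercept)), float(slope)
    else:  # linear_origin
        a = float(np.sum(pressure * flow) / np.sum(pressure**2))
        b = 1.0
        if a <= 0:
            raise ValueError("linear-origin fit produced a non-positive slope")

    predicted = a * pressure**b
    ss_res = float(np.sum((flow - predicted) ** 2))
    ss_tot = float(np.sum((flow - flow.mean()) ** 2))

    if np.ptp(flow) == 0:
        # constant flows: correlation undefined, no variance to explain
        pearson_r, p_value, r_squared = float("nan"), float("nan"), 0.0
    else:
        pearson_r, p_value = stats.pearsonr(pressure, flow)
        r_squared = max(0.0, 1.0 - ss_res / ss_tot)

    return FlowPressureModel(
        fluid=fluid,
        wound=wound,
        form=form,
        coefficient_a=a,
        exponent_b=b,
        pearson_r=float(pearson_r),
        r_squared=float(r_squared),
        p_value=float(p_value),
        n=len(measurements),
        dropped_zero_flows=dropped,
    )


def predict_flow(model: FlowPressureModel, pressure_mmhg: float) -> float:
    """Evaluate the fitted relation at a gauge pressure (mmHg)."""
    if not isinstance(model, FlowPressureModel):
        raise ValueError("predict_flow requires a fitted FlowPressureModel")
    if pressure_mmhg < 0:
        raise ValueError(f"pressure must be non-negative, got {pressure_mmhg}")
    if pressure_mmhg == 0:
        return 0.0
    return model.coefficient_a * pressure_mmhg**model.exponent_b


def compare_conditions(
    models: Sequence[FlowPressureModel],
    pressure_grid: Iterable[float],
) -> pd.DataFrame:
    """Tabulate predicted flows for each model over a pressure grid.

    Returns a tidy frame with one row per (model, pressure), preserving
    the input ordering of both.
    """
    models = list(models)
    grid = [float(p) for p in pressure_grid]
    if not models:
        raise ValueError("need at least one fitted model")
    if not grid:
        raise ValueError("pressure grid must be non-empty")
    rows = [
        {
            "fluid": m.fluid,
            "wound": m.wound,
            "pressure_mmhg": p,
            "flow_ml_min": predict_flow(m, p),
        }
        for m in models
        for p in grid
    ]
    return pd.DataFrame(rows, columns=["fluid", "wound", "pressure_mmhg", "flow_ml_min"])
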