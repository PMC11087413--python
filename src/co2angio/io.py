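"""CSV / JSON reading, writing, and validation.

One canonical measurement table dialect is supported: comma-separated,
UTF-8, "." decimal separator, mandatory header with columns ``fluid``,
``wound``, ``pressure_mmHg``, ``flow_mL_min`` and an optional boolean
``corrected`` column.  The only unit leniency is a kPa flag on read,
converting the pressure column by 7.50062 mmHg/kPa.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .flow_model import FlowPressureModel, SteadyStateMeasurement
from .physics import MMHG_PER_KPA, PressureEnvironment, boyle_correct
from .physics import CO2 as _CO2

__all__ = [
    "FLUID_ALIASES",
    "WOUND_ALIASES",
    "canonical_fluid",
    "canonical_wound",
    "read_measurements_csv",
    "write_measurements_csv",
    "validate_measurements",
    "models_to_json",
    "models_from_json",
]

REQUIRED_COLUMNS = ("fluid", "wound", "pressure_mmHg", "flow_mL_min")

FLUID_ALIASES = {
    "co2": "co2",
    "co_2": "co2",
    "carbon dioxide": "co2",
    "carbondioxide": "co2",
    "gas": "co2",
    "iodine": "iodine",
    "iodinated": "iodine",
    "omnipaque": "iodine",
    "iodine contrast": "iodine",
}

WOUND_ALIASES = {
    "small": "small",
    "27": "small",
    "27g": "small",
    "27-gauge": "small",
    "large": "large",
    "big": "large",
    "significant": "large",
    "18": "large",
    "18g": "large",
    "18-gauge": "large",
}


def canonical_fluid(label: str) -> str:
    key = str(label).strip().lower()
    if key not in FLUID_ALIASES:
        raise ValueError(f"unknown fluid label {label!r}")
    return FLUID_ALIASES[key]


def canonical_wound(label: str) -> str:
    key = str(label).strip().lower()
    if key not in WOUND_ALIASES:
        raise ValueError(f"unknown wound label {label!r}")
    return WOUND_ALIASES[key]


def validate_measurements(
    frame: pd.DataFrame,
    pressure_in_kpa: bool = False,
    env: PressureEnvironment | None = None,
) -> list[SteadyStateMeasurement]:
    """Turn a parsed measurement table into validated measurements.

    Labels are normalized to the canonical fluid/wound vocabulary; rows
    with ``corrected == False`` for a compressible fluid receive the
    isothermal expansion correction here.  Errors name the offending
    1-based data row.  Duplicate rows trigger a warning, not an error.
    """
    if frame.empty:
        raise ValueError("no data: measurement table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    env = env or PressureEnvironment()

    if frame.duplicated(subset=list(REQUIRED_COLUMNS)).any():
        dupes = frame.index[frame.duplicated(subset=list(REQUIRED_COLUMNS))].tolist()
        warnings.warn(f"duplicate measurement row(s): {[i + 1 for i in dupes]}", stacklevel=2)

    measurements = []
    for idx, row in frame.iterrows():
        rownum = idx + 1
        try:
            fluid = canonical_fluid(row["fluid"])
            wound = canonical_wound(row["wound"])
            pressure = float(row["pressure_mmHg"])
            flow = float(row["flow_mL_min"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
        if pressure_in_kpa:
            pressure *= MMHG_PER_KPA
        corrected = True
        if "corrected" in frame.columns:
            corrected = _parse_bool(row["corrected"], rownum)
        if not corrected and fluid == "co2":
            flow = boyle_correct(flow, pressure, env, _CO2)
        try:
            measurements.append(SteadyStateMeasurement(fluid, wound, pressure, flow))
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    return measurements


def _parse_bool(value, rownum: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"row {rownum}: cannot interpret corrected={value!r} as boolean")


def read_measurements_csv(
    path: str | Path,
    pressure_in_kpa: bool = False,
    env: PressureEnvironment | None = None,
) -> list[SteadyStateMeasurement]:
    """Read and validate a measurement CSV (see module docstring)."""
    frame = pd.read_csv(path, encoding="utf-8")
    return validate_measurements(frame, pressure_in_kpa=pressure_in_kpa, env=env)


def write_measurements_csv(
    measurements: Sequence[SteadyStateMeasurement],
    path: str | Path,
) -> None:
    """Write measurements in the canonical dialect (all flows corrected)."""
    frame = pd.DataFrame(
        {
            "fluid": [m.fluid for m in measurements],
            "wound": [m.wound for m in measurements],
            "pressure_mmHg": [m.pressure_mmhg for m in measurements],
            "flow_mL_min": [m.flow_ml_min for m in measurements],
            "corrected": [True] * len(measurements),
        }
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def models_to_json(models: Sequence[FlowPressureModel], path: str | Path) -> None:
    payload = {"models": [m.to_dict() for m in models]}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def models_from_json(path: str | Path) -> list[FlowPressureModel]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [FlowPressureModel.from_dict(d) for d in payload["models"]]
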