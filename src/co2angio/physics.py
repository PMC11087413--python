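"""Physical constants, unit conventions, and closed-form physics.

Units used throughout the package:

* pressure — mmHg, gauge relative to atmosphere unless stated absolute
* volumetric flow — mL/min
* volume — mL (converted to mm^3 inside the geometry helpers)
* length — mm
* dynamic viscosity — cP

All unit conversions live here; every other module works in these
coherent units and never converts on its own.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "PA_PER_MMHG",
    "MMHG_PER_KPA",
    "MMHG_PER_CMH2O",
    "ATMOSPHERIC_MMHG",
    "INTRA_ABDOMINAL_MMHG",
    "WATER_COLUMN_CM",
    "VISCOSITY_CP",
    "Fluid",
    "PressureEnvironment",
    "WoundSpec",
    "IODINE",
    "CO2",
    "SMALL_WOUND",
    "LARGE_WOUND",
    "boyle_correct",
    "poiseuille_flow",
    "sphere_equivalent_diameter",
    "projected_circle_area",
    "mmhg_from_kpa",
    "mmhg_from_cmh2o",
]

PA_PER_MMHG = 133.322387415
MMHG_PER_KPA = 7.50061682704
MMHG_PER_CMH2O = 0.7355591353

#: Absolute atmospheric pressure assumed for the isothermal gas correction.
ATMOSPHERIC_MMHG = 760.0
#: Gauge back-pressure outside the vessel wound (abdominal cavity analogue).
INTRA_ABDOMINAL_MMHG = 6.0
#: Water-column height emulating the intra-abdominal back-pressure
#: (8 cmH2O = 5.88 mmHg, rounded to the 6 mmHg used in all computations).
WATER_COLUMN_CM = 8.0

#: Dynamic viscosities at 37 degC and 1 atm, cP.  Blood spans 3-4 cP with
#: hematocrit; non-ionic iodinated contrast 9.1-10.6 cP (midpoint used);
#: the CO2 default is configurable because reported values for the gas
#: vary by an order of magnitude between sources.
VISCOSITY_CP = {
    "blood": 3.5,
    "iodine": 9.85,
    "co2": 0.0013,
}


@dataclass(frozen=True)
class Fluid:
    """An injectable contrast medium.

    Parameters
    ----------
    name:
        Canonical lower-case label ("iodine", "co2", ...).
    viscosity_cp:
        Dynamic viscosity in cP at 37 degC and 1 atm; must be positive.
    compressible:
        True for gases (subject to the isothermal expansion correction),
        False for liquids.
    """

    name: str
    viscosity_cp: float
    compressible: bool

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("fluid name must be non-empty")
        if not (self.viscosity_cp > 0):
            raise ValueError(f"viscosity must be positive, got {self.viscosity_cp}")


@dataclass(frozen=True)
class PressureEnvironment:
    """Ambient pressures bracketing the vessel wound.

    ``atmospheric`` is absolute; ``intra_abdominal`` is gauge (relative to
    atmosphere).  ``water_column_cm`` records the physical head used to
    impose the back-pressure; the mmHg value is authoritative.
    """

    atmospheric: float = ATMOSPHERIC_MMHG
    intra_abdominal: float = INTRA_ABDOMINAL_MMHG
    water_column_cm: float = WATER_COLUMN_CM

    def __post_init__(self) -> None:
        if not (self.atmospheric > 0):
            raise ValueError("atmospheric pressure must be positive")
        if self.intra_abdominal < 0:
            raise ValueError("intra-abdominal pressure must be non-negative")
        equivalent = self.water_column_cm * MMHG_PER_CMH2O
        if abs(equivalent - self.intra_abdominal) > 1.0:
            warnings.warn(
                f"water column of {self.water_column_cm} cm corresponds to "
                f"{equivalent:.2f} mmHg, not the configured intra-abdominal "
                f"{self.intra_abdominal} mmHg",
                stacklevel=2,
            )


@dataclass(frozen=True)
class WoundSpec:
    """A needle perforation in the 4 mm-lumen simulated vessel.

    ``effective_radius_mm`` parameterizes the simulator's orifice only; it
    is a hydraulic radius, not a measured wound geometry, and never appears
    in reported quantities.
    """

    label: str
    gauge: int
    effective_radius_mm: float

    def __post_init__(self) -> None:
        if self.label not in ("small", "large"):
            raise ValueError(f"wound label must be 'small' or 'large', got {self.label!r}")
        if not (self.effective_radius_mm > 0):
            raise ValueError("effective radius must be positive")


IODINE = Fluid("iodine", VISCOSITY_CP["iodine"], compressible=False)
CO2 = Fluid("co2", VISCOSITY_CP["co2"], compressible=True)

# Nominal needle outer radii: 27G ~0.41 mm OD, 18G ~1.27 mm OD.
SMALL_WOUND = WoundSpec("small", gauge=27, effective_radius_mm=0.205)
LARGE_WOUND = WoundSpec("large", gauge=18, effective_radius_mm=0.635)


def boyle_correct(
    flow_ml_min: float,
    p_intravascular: float,
    env: PressureEnvironment,
    fluid: Fluid,
) -> float:
    """Rescale a gas flow from intravascular to extravascular conditions.

    A compressible medium leaving the vessel expands isothermally from the
    intravascular absolute pressure to the intra-abdominal absolute
    pressure, so the escaped volume per unit time grows by the ratio of
    absolute pressures::

        Q_out = Q_in * (P_atm + P_intravascular) / (P_atm + P_abdominal)

    Liquids are returned unchanged.

    Parameters
    ----------
    flow_ml_min:
        Leakage flow at intravascular conditions, mL/min; non-negative.
    p_intravascular:
        Gauge intravascular pressure, mmHg; non-negative.
    env, fluid:
        Ambient pressures and the medium being corrected.
    """
    if flow_ml_min < 0:
        raise ValueError(f"flow must be non-negative, got {flow_ml_min}")
    if p_intravascular < 0:
        raise ValueError(f"intravascular pressure must be non-negative, got {p_intravascular}")
    if not fluid.compressible:
        return flow_ml_min
    ratio = (env.atmospheric + p_intravascular) / (env.atmospheric + env.intra_abdominal)
    return flow_ml_min * ratio


def poiseuille_flow(
    delta_p_mmhg: float,
    radius_mm: float,
    length_mm: float,
    viscosity_cp: float,
) -> float:
    """Hagen-Poiseuille laminar flow through a cylindrical conduit.

    Q = pi * dP * r^4 / (8 * mu * L), evaluated in SI and returned in
    mL/min.  A non-positive driving pressure yields zero flow (no
    backflow), keeping the leak law one-sided.
    """
    if not (radius_mm > 0):
        raise ValueError("radius must be positive")
    if not (length_mm > 0):
        raise ValueError("length must be positive")
    if not (viscosity_cp > 0):
        raise ValueError("viscosity must be positive")
    if delta_p_mmhg <= 0:
        return 0.0
    dp_pa = delta_p_mmhg * PA_PER_MMHG
    r_m = radius_mm * 1e-3
    length_m = length_mm * 1e-3
    mu_pas = viscosity_cp * 1e-3
    q_m3_s = math.pi * dp_pa * r_m**4 / (8.0 * mu_pas * length_m)
    return q_m3_s * 1e6 * 60.0  # m^3/s -> mL/min


def sphere_equivalent_diameter(volume_ml: float) -> float:
    """Diameter (mm) of the sphere whose volume equals ``volume_ml``.

    d = (6 V / pi)^(1/3) with V in mm^3 (1 mL = 1000 mm^3).  The disc of
    this sphere is the "equivalent circle" used as a fluoroscopic
    visibility proxy for a leaked contrast blob.
    """
    if volume_ml < 0:
        raise ValueError(f"volume must be non-negative, got {volume_ml}")
    v_mm3 = volume_ml * 1000.0
    return (6.0 * v_mm3 / math.pi) ** (1.0 / 3.0)


def projected_circle_area(diameter_mm: float) -> float:
    """Area (mm^2) of the great-circle disc of a sphere of given diameter."""
    if diameter_mm < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_mm}")
    return math.pi * diameter_mm**2 / 4.0


def mmhg_from_kpa(p_kpa: float) -> float:
    return p_kpa * MMHG_PER_KPA


def mmhg_from_cmh2o(h_cm: float) -> float:
    return h_cm * MMHG_PER_CMH2O
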