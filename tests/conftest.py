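import pytest

from co2angio.flow_model import SteadyStateMeasurement, fit_flow_pressure
from co2angio.physics import PressureEnvironment
from co2angio.visibility import ShotConfig


@pytest.fixture(scope="session")
def env() -> PressureEnvironment:
    return PressureEnvironment()


@pytest.fixture(scope="session")
def shot() -> ShotConfig:
    return ShotConfig()


def power_law_model(fluid: str, wound: str, a: float, b: float):
    """Exactly fitted power-law model with given coefficients.

    Built by fitting noise-free data generated from the target law, so the
    returned model went through the real fitting path.
    """
    pressures = [50.0, 100.0, 150.0, 200.0]
    ms = [
        SteadyStateMeasurement(fluid, wound, p, a * p**b)
        for p in pressures
    ]
    return fit_flow_pressure(ms, form="power_law")


@pytest.fixture(scope="session")
def calibrated_models():
    """Four-condition models matching the reference 100 mmHg anchors.

    Corrected flows at 100 mmHg: iodine 0.05 / 1.5 mL/min (small/large),
    CO2 4.52 / 121 mL/min; laminar exponent for the liquid, near-orifice
    exponent for the gas.
    """
    anchors = {
        ("iodine", "small"): (0.05, 1.0),
        ("iodine", "large"): (1.5, 1.0),
        ("co2", "small"): (4.52, 0.55),
        ("co2", "large"): (121.0, 0.55),
    }
    return {
        cond: power_law_model(cond[0], cond[1], q100 / 100.0**b, b)
        for cond, (q100, b) in anchors.items()
    }
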