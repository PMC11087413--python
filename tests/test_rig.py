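"""Synthetic injection rig: traces, steady-state detection, experiments."""

from dataclasses import replace

import numpy as np
import pytest

from co2angio.physics import CO2, IODINE, SMALL_WOUND, PressureEnvironment
from co2angio.rig import (
    PressureTrace,
    RigConfig,
    RigError,
    detect_steady_state,
    generate_experiment,
    orifice_bench_configs,
    reference_conditions,
    simulate_pressure_trace,
)


def linear_rig(a=0.0005, q_in=0.05, compliance=0.01, duration=200.0, noise=0.0, seed=0):
    """A b = 1 configuration with known closed-form relaxation."""
    return RigConfig(
        fluid=IODINE,
        wound=SMALL_WOUND,
        compliance_ml_per_mmhg=compliance,
        conductance_a=a,
        exponent_b=1.0,
        injection_rate_ml_min=q_in,
        back_pressure_mmhg=6.0,
        noise_cv=noise,
        seed=seed,
        duration_min=duration,
        dt_min=duration / 800,
    )


class TestSimulatePressureTrace:
    def test_no_injection_gives_flat_trace_at_back_pressure(self):
        cfg = linear_rig(q_in=0.0)
        trace = simulate_pressure_trace(cfg)
        assert np.allclose(trace.pressures_mmhg, 6.0, atol=1e-9)

    def test_matches_closed_form_exponential_relaxation(self):
        """b = 1, noise-free: P(t) = P_back + (Q/a)(1 - exp(-a t / C))."""
        cfg = linear_rig()
        trace = simulate_pressure_trace(cfg)
        tau = cfg.compliance_ml_per_mmhg / cfg.conductance_a
        analytic = 6.0 + (0.05 / 0.0005) * (1.0 - np.exp(-trace.times_min / tau))
        rel = np.abs(trace.pressures_mmhg - analytic) / np.maximum(analytic, 1.0)
        assert rel.max() < 1e-3

    def test_plateau_at_analytic_steady_pressure(self):
        cfg = linear_rig()
        trace = simulate_pressure_trace(cfg)
        # Q_in = a (P_ss - 6)  ->  P_ss = 106 mmHg
        assert cfg.steady_pressure() == pytest.approx(106.0, rel=1e-12)
        assert trace.pressures_mmhg[-1] == pytest.approx(106.0, rel=1e-3)

    def test_noise_free_trace_is_non_decreasing(self):
        trace = simulate_pressure_trace(linear_rig())
        assert np.all(np.diff(trace.pressures_mmhg) >= -1e-9)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_pressure_trace(linear_rig(noise=0.02, seed=7))
        b = simulate_pressure_trace(linear_rig(noise=0.02, seed=7))
        c = simulate_pressure_trace(linear_rig(noise=0.02, seed=8))
        assert np.array_equal(a.pressures_mmhg, b.pressures_mmhg)
        assert not np.array_equal(a.pressures_mmhg, c.pressures_mmhg)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError, match="exponent"):
            replace(linear_rig(), exponent_b=2.0)


class TestDetectSteadyState:
    def test_constant_trace_returns_its_level(self):
        t = np.arange(100) * 0.1
        trace = PressureTrace(t, np.full(100, 80.0))
        assert detect_steady_state(trace, window=20, slope_tol_mmhg_min=0.5) == pytest.approx(80.0)
        assert trace.steady_reached

    def test_exponential_run_ten_time_constants_hits_asymptote(self):
        cfg = linear_rig(duration=200.0)  # tau = 20 min -> 10 tau
        trace = simulate_pressure_trace(cfg)
        steady = detect_steady_state(trace, window=80, slope_tol_mmhg_min=0.05)
        assert steady == pytest.approx(106.0, rel=5e-3)

    def test_linearly_increasing_trace_never_stabilizes(self):
        t = np.arange(200) * 0.1
        trace = PressureTrace(t, 10.0 + 5.0 * t)
        assert detect_steady_state(trace, window=50, slope_tol_mmhg_min=1.0) is None
        assert not trace.steady_reached

    def test_window_larger_than_trace_rejected(self):
        trace = PressureTrace(np.arange(10.0), np.full(10, 5.0))
        with pytest.raises(ValueError, match="window"):
            detect_steady_state(trace, window=20)


class TestGenerateExperiment:
    def test_liquid_conservation_noise_free(self, env):
        """At the plateau the leak exactly balances the injection."""
        cfg = linear_rig(noise=0.0, duration=600.0)  # 30 time constants
        [m] = generate_experiment([cfg], env)
        leak = cfg.leak_flow(m.pressure_mmhg)
        assert abs(leak - cfg.injection_rate_ml_min) / cfg.injection_rate_ml_min < 1e-6
        assert m.flow_ml_min == cfg.injection_rate_ml_min  # liquid: no correction

    def test_gas_flow_recorded_with_expansion_correction(self, env):
        cfg = replace(linear_rig(noise=0.0, duration=600.0), fluid=CO2,
                      injection_rate_ml_min=1.0, conductance_a=0.01)
        [m] = generate_experiment([cfg], env)
        assert m.pressure_mmhg == pytest.approx(106.0, rel=1e-4)
        expected = 1.0 * (760.0 + m.pressure_mmhg) / 766.0
        assert m.flow_ml_min == pytest.approx(expected, rel=1e-12)

    def test_experiment_tables_bit_reproducible(self, env):
        runs = []
        for _ in range(2):
            configs = reference_conditions(seed=11)
            runs.append(generate_experiment(configs, env))
        assert [(m.pressure_mmhg, m.flow_ml_min) for m in runs[0]] == [
            (m.pressure_mmhg, m.flow_ml_min) for m in runs[1]
        ]

    def test_non_stabilizing_config_identified(self, env):
        # plateau at 30 time constants but only 0.5 simulated: still rising
        cfg = replace(linear_rig(noise=0.0), duration_min=10.0, dt_min=10.0 / 800)
        with pytest.raises(RigError, match="iodine/small"):
            generate_experiment([cfg], env, window=200, slope_tol_mmhg_min=0.01)


class TestReferenceConditions:
    def test_four_conditions_six_pressures(self):
        configs = reference_conditions(seed=0)
        assert len(configs) == 24
        conditions = {(c.fluid.name, c.wound.label) for c in configs}
        assert conditions == {("iodine", "small"), ("iodine", "large"),
                              ("co2", "small"), ("co2", "large")}

    def test_steady_pressures_hit_targets(self):
        targets = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0)
        for cfg in reference_conditions(seed=0, target_pressures=targets):
            assert any(cfg.steady_pressure() == pytest.approx(t, rel=1e-9) for t in targets)

    def test_corrected_anchor_flows_at_100(self, env):
        """The calibration puts each condition's corrected flow at its
        100 mmHg anchor by construction."""
        from co2angio.physics import boyle_correct
        from co2angio.rig import REFERENCE_FLOW_AT_100

        configs = reference_conditions(seed=0, target_pressures=(100.0,))
        for cfg in configs:
            anchor = REFERENCE_FLOW_AT_100[(cfg.fluid.name, cfg.wound.label)]
            corrected = boyle_correct(cfg.leak_flow(100.0), 100.0, env, cfg.fluid)
            assert corrected == pytest.approx(anchor, rel=1e-12)

    def test_gas_conductance_exceeds_liquid_conductance(self):
        """Lower gas viscosity must translate into a larger leak
        coefficient for the same wound."""
        configs = {(c.fluid.name, c.wound.label): c
                   for c in reference_conditions(seed=0, target_pressures=(100.0,))}
        assert configs[("co2", "small")].conductance_a > configs[("iodine", "small")].conductance_a
        assert configs[("co2", "large")].conductance_a > configs[("iodine", "large")].conductance_a

    def test_poiseuille_conductance_ordering_with_wound_radii(self):
        """With laminar leaks sized by the calibrated hydraulic radii, the
        gas/liquid conductance ratio follows the inverse viscosity ratio,
        so a small gas wound can out-leak a large liquid wound when
        r_small^4 / mu_gas > r_large^4 / mu_liquid."""
        from co2angio.physics import LARGE_WOUND, poiseuille_flow

        wall = 1.0  # mm, vessel wall thickness traversed by the needle
        q_gas_small = poiseuille_flow(94.0, SMALL_WOUND.effective_radius_mm, wall,
                                      CO2.viscosity_cp)
        q_liq_small = poiseuille_flow(94.0, SMALL_WOUND.effective_radius_mm, wall,
                                      IODINE.viscosity_cp)
        q_liq_large = poiseuille_flow(94.0, LARGE_WOUND.effective_radius_mm, wall,
                                      IODINE.viscosity_cp)
        assert q_gas_small / q_liq_small == pytest.approx(
            IODINE.viscosity_cp / CO2.viscosity_cp, rel=1e-9
        )
        assert q_gas_small > q_liq_large
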