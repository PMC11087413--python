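# Methods

## Problem setting

A perforated vessel leaks contrast medium at a rate set by the
intravascular pressure, the wound geometry, and the injectate's physical
properties. During angiography the question is not the leak rate itself
but whether the leaked contrast is *visible* on a two-dimensional
fluoroscopic image. This package models the full chain for two media —
iodinated contrast (a viscous liquid, ~9–10.6 cP at 37 °C) and CO₂ (a
gas, orders of magnitude less viscous and compressible) — through a
"small" (27G needle) or "large" (18G needle) perforation of a 4 mm-lumen
vessel held under a 6 mmHg external back-pressure.

## Units and constants

Pressures are mmHg (gauge relative to atmosphere unless stated absolute),
flows mL/min, volumes mL (mm³ inside the geometry helpers), lengths mm,
viscosities cP. All conversions are centralized in `co2angio.physics`.

Defaults: atmospheric pressure 760 mmHg; intra-abdominal back-pressure
6 mmHg. The rig's 8 cm water column corresponds to 5.88 mmHg; the two are
treated as the same quantity with the 6 mmHg value authoritative in every
computation (constructing a `PressureEnvironment` whose column disagrees
by more than 1 mmHg warns). Viscosities: blood 3.5 cP (3–4 cP range with
hematocrit), iodinated contrast 9.85 cP (9.1–10.6 cP range midpoint), CO₂
0.0013 cP by default. Reported CO₂ viscosity values differ by an order of
magnitude between sources (~0.015 cP is also commonly quoted); the value
is a `Fluid` parameter, not a hard-coded constant, and none of the
reported metrics depend on it — it only enters the Poiseuille helper and
the conductance-ordering argument, both of which are insensitive to the
choice within that range.

## Gas expansion correction

A compressible medium leaving the vessel expands isothermally from the
intravascular absolute pressure to the extravascular (intra-abdominal)
absolute pressure:

    Q_out = Q_in · (760 + P) / (760 + 6).

The convention — inlet absolute = atmospheric + intravascular gauge,
outlet absolute = atmospheric + intra-abdominal gauge, isothermal at
37 °C — is the simplest consistent reading of gas expanding out of a
vessel into the abdominal cavity. Liquids pass through unchanged.
Real-gas behavior and temperature transients are out of scope.

## Flow–pressure model

The functional form linking leakage flow to intravascular pressure is not
dictated by first principles for a torn silicone wall: a viscous-laminar
leak gives Q ∝ ΔP (Hagen–Poiseuille), an inertial orifice gives
Q ∝ ΔP^0.5. The default model is therefore the power law `Q = a·P^b`,
which spans both regimes; a line through the origin is available as the
alternative. Power-law coefficients are estimated by least squares in
log–log space (zero-flow points carry no log-space information and are
dropped with a warning); the through-origin line has the closed form
`a = ΣPQ/ΣP²`. Pearson r and its two-sided p-value are computed on the
original (P, Q) scale, as is R² = 1 − SS_res/SS_tot, so fit quality is
comparable across forms. Degenerate input (fewer than 3 points, a single
distinct pressure) is rejected; all-equal flows yield an undefined
(NaN) correlation with R² = 0 rather than an error. R² is floored at 0.

The measured intravascular pressure is taken as gauge relative to
atmosphere (not relative to the bath outlet); the fit is performed on
that scale.

## Visibility metrics

With a fasting superior-mesenteric-artery flow of 200 mL/min and a 20 mL
shot, the bolus passes the bleeding point in 0.1 min. Per-shot leak
volume is `Q(P) × 0.1 min`; the "equivalent sphere/circle" construction
shapes that volume into a sphere of diameter `d = (6V/π)^(1/3)` (V in
mm³) whose great-circle disc `A = πd²/4` proxies the leak's footprint on
the 2-D image. This chain reproduces the internally consistent worked
values (0.15 mL → 6.59 mm → 34.1 mm²; 12.1 mL → 28.5 mm → 637 mm²).
Internal computation is full precision; presentation rounds to 3
significant figures, and CO₂/iodine ratios are computed from unrounded
values before rounding. X-ray attenuation, contrast-to-noise, buoyancy
and dispersion of the leaked gas are explicitly not modelled: the area is
a geometric proxy, not an imaging-physics prediction.

## Synthetic rig

The physical apparatus — motor-driven glass syringe, Tygon tubing,
simulated vessel and pressure transducer in a 37 °C bath — is modelled as
a single lumped compliance charged at the injection rate and discharged
through a static orifice:

    C dP/dt = Q_in − a·max(P − P_back, 0)^b,     P(0) = P_back.

The pressure rises and saturates at the stabilization plateau P_ss where
the leak balances the injection, matching the rise-then-plateau character
of recorded traces. Integration uses `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-9), which matches the b = 1 closed-form relaxation
`P(t) = P_back + (Q_in/a)(1 − e^(−at/C))` to better than 0.1%.
Multiplicative Gaussian noise (default CV 2%) models transducer readout;
the syringe drive is treated as noise-free. Gas runs are simulated in
intravascular volume units with the expansion correction applied only
when a measurement is recorded, consistent with correcting measured
flows rather than simulating gas dynamics.

Steady-state detection fits a least-squares line to the trailing window
of the trace (defaults in `generate_experiment`: 200 samples, slope
tolerance 2 mmHg/min) and accepts the window mean as the stabilization
pressure when the slope magnitude is within tolerance. Because the
noise-free dynamics are monotone toward the plateau, a still-rising tail
implies no earlier window is flatter, so only the trailing window is
examined; a trace that never flattens raises an error naming the
offending configuration. The window/tolerance defaults sit several
standard deviations above the slope jitter induced by 2% readout noise
at the default sampling (1,200 samples over 12 time constants), so
plateau detection is reliable without masking genuine drift.

### Calibration (the study conditions)

No compliance or injection-rate values are prescribed by the physical
rig, so the simulator's defaults are chosen as follows and not revisited:

* **Anchors.** Each condition's conductance is set so its *corrected*
  flow at 100 mmHg equals the reference values: iodine 0.05 / 1.5 mL/min
  and CO₂ 4.52 / 121 mL/min (small / large wound). The large-wound
  anchors correspond to per-shot volumes of 0.15 and 12.1 mL.
* **Exponents.** b = 1.0 for the liquid (viscous laminar leak) and
  b = 0.55 for the gas, whose ~1000× lower viscosity pushes the leak
  into an inertial, near-orifice regime. This choice also yields the
  observed qualitative behavior: CO₂/iodine visibility ratios that fall
  with pressure and nearly coincide for the two wound sizes.
* **Operating points.** Six target stabilization pressures per condition
  (25–150 mmHg, step 25); injection rates are back-solved from the leak
  law. These per-point rates are an invented experimental design — the
  `measurements.csv` metadata records them via the embedded
  configuration.
* **Time scales.** Compliance is set per run so the relaxation time
  constant τ = C/(a·b·(P_ss−P_back)^(b−1)) is 1 min, and each trace runs
  12 τ at 1,200 samples, so every run plateaus well inside its duration.
  These sizes keep a full four-condition experiment under a couple of
  seconds while leaving plateau residuals (~e⁻¹⁰ of the pressure step)
  far below the noise floor.
* **Seeding.** One `numpy.random.SeedSequence(seed)` spawns per-run
  seeds in condition-major, pressure-minor order; tables are
  bit-reproducible for a fixed seed.

### Parameter recovery and the back-pressure offset

Under the 6 mmHg back-pressure the generating law is a power of
(P − 6) while the fitted model is a power of P. The two families differ
by a pressure offset, so the generating *prefactor* is not identifiable
from the fit (fitting `a·Pᵇ` to exact `a·(P−6)ᵇ` data over 25–150 mmHg
shifts the recovered prefactor by tens of percent while R² stays above
0.998 and predicted flows at 100 mmHg stay within ~1%). Coefficient
recovery is therefore assessed on a vented-outlet bench configuration
(`orifice_bench_configs`, back-pressure 0), where the stabilization
pressure *is* the orifice driving pressure and the forms coincide:
there, the median conductance error over 200 seeded replicates at 2%
readout noise is ~0.3%. Under the reference (6 mmHg) conditions, fit
quality is judged by R² and by predicted flows at the 100 mmHg anchors
(within 2%).

## What the synthetic data do and do not show

The generator reproduces the features the analysis relies on: monotone
rise to a plateau, conservation of flow at steady state, a smooth
single-valued flow–pressure relation per condition, transducer-like
readout noise, and the gas expansion on exit. It does not emulate
pulsatile or circulating flow, contrast–blood mixing, vessel meandering,
elastic vessel-wall response beyond lumped compliance, vascular spasm or
thrombus formation, or any imaging physics. Passing tests therefore
demonstrate that the analysis pipeline is correct and self-consistent
under these idealized conditions — not that a physical rig or a patient
would produce these numbers.

## Numerical choices and known discrepancies

* No backflow: non-positive driving pressure yields zero flow.
* The worked-value chain is self-consistent except one documented case:
  a 0.005 mL per-shot volume corresponds to a 2.12 mm sphere, while the
  commonly quoted small-wound iodine diameter of 2.19 mm arises from an
  unrounded fitted flow (~0.055 mL/min). The package reproduces the
  self-consistent subset (2.12 mm from 0.005 mL) and treats 2.19 mm as a
  rounding artifact of upstream intermediates; for the same reason the
  chain yields 0.452 mL (not 0.457 mL) from the 4.52 mL/min anchor and
  637 mm² (not 639.5 mm²) from 12.1 mL, each within ~1%.
* CSV dialect: comma-separated, UTF-8, "." decimal, mandatory header;
  the only unit leniency is a kPa flag (×7.50062 to mmHg) on read.
  Fluid/wound labels are normalized to a canonical vocabulary
  ("CO2"/"carbon dioxide" → `co2`; "18G"/"big" → `large`; ...).
* Reports embed the full effective configuration (defaults, seed,
  package version) and contain no timestamps, so repeated runs with the
  same seed are byte-identical.
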