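# Methods

## Hydraulic model

The solver treats incompressible, laminar, quasi-static flow through a
network of lumped elements, using the standard electrical analogy: pressure
is voltage, volumetric flow is current, and each element contributes a
hydraulic resistance R_h with ΔP = Q·R_h.

Element formulas:

- **Rectangular channel**: R_h ≈ 12µL / (w·h³·(1 − 0.63·α)) with aspect
  ratio α = min(w,h)/max(w,h). The correction uses min/max so it stays in
  (0, 1] whichever way the cross-section is specified. This is the usual
  one-term truncation of the exact series solution; for near-square
  channels the truncation itself is ~10–15% off the exact value, an error
  of the approximation, not of the implementation.
- **Circular tube**: R_h = 128µL/(πd⁴).
- **Fixed resistor**: a lumped R_h for components whose internal geometry
  is not resolved (flow sensors, connectors, whole chips).
- **Check valve**: ideal diode with cracking pressure P_c (default 0) and
  open-state forward resistance R_f. When open it carries
  Q = (ΔP − P_c)/R_f ≥ 0; when closed it carries exactly zero flow.
  Commercial valve characteristics are not published for the parts
  modelled, so R_f defaults to 10⁻³ × the smallest fixed resistance in the
  network — small enough not to perturb the sample flows it guards.

The parallel reduction is implemented as 1/R_tot = Σ 1/R_i, the standard
law for parallel branches.

**Nodal solve.** Internal node pressures satisfy Kirchhoff's current law;
the conductance matrix is assembled over internal nodes with terminals as
Dirichlet boundary values and open-valve cracking pressures as series
EMFs. Valve states are found by a deterministic active-set iteration:
start with every valve open; at each iteration compute the
complementarity violations in pressure units (an open valve with negative
flow is violated by P_c − ΔP, a closed valve with forward drop above
cracking by ΔP − P_c), flip the single most-violated valve (ties broken by
element order), and stop when no violation remains, with an iteration cap
of 2^(number of valves). Matrices are small (tens of nodes); closed valves
can isolate nodes, in which case the pseudo-inverse pins the floating
pressures and the flows (all zero there) are unaffected. The per-assignment
inverse is cached so time-domain simulation costs one matrix–vector product
per step once the valve pattern has been visited.

Tolerances: reverse flow below 10⁻¹⁸ m³/s and cracking slack below
10⁻⁹ Pa are treated as satisfied; the KCL residual of a converged solve is
reported in the solution for diagnostics and is at roundoff (relative
~10⁻¹²) in the test networks.

## Plant

Reservoirs are cylinders (default 14 mm inner diameter for a 15 mL tube);
the conical tip is folded into a dead volume (default 1 mL) below the
outlet. The hydrostatic head is ρg·V/A, linear in stored volume, so the
combined loss of driving pressure per displaced mL between two reservoirs
is ρg(1/A₁ + 1/A₂) — ≈1.27 mbar/mL for two standard tubes of water, rising
with density (≈1.38 at 1080 kg/m³). Densities default to 1000 kg/m³
(water) and 1005 kg/m³ (culture medium).

Pneumatic channels are first-order lags toward the commanded pressure,
integrated exactly per step, with separate pressurise (0.3 s) and vent
time constants, and the two channels deliberately asymmetric (vents of
2.0 s and 1.0 s). These are calibration values chosen so that a full
command reversal settles in roughly 4–8 s, the behaviour observed on
bench-grade pressure controllers; they are not device constants. Command
range is clamped to 0–345 mbar.

Each `step(dt)` advances the pneumatics, solves the circuit at the
instantaneous reservoir bottom pressures (air + head), and transfers Q·dt
between the reservoirs as a single increment, so total liquid volume is
conserved to roundoff by construction. Volumes are clamped at the dead
volume with a dry-run flag. Default dt is 0.01 s (the 100 Hz sensor rate);
a dt above one fifth of the fastest pneumatic time constant triggers a
warning. Air-side compressibility and tubing compliance are out of scope.

## Sensors

- **Flow sensor**: measured = clip(g·Q_true + ε, range), with ranges
  matching the size-L (−1100…+1000 µL/min) and size-XL (±5500 µL/min)
  commercial parts. The fouling gain g ∈ (0, 1] is a free parameter: real
  fouling kinetics are uncharacterised, and the constant gain reproduces
  the endpoint that matters — a fouled sensor under-reads, and fixed-flow
  feedback on it drives the true flow to setpoint/g (4× at g = 0.25). The
  closed-loop failure mode is available both as the closed form and as an
  actual integral-feedback simulation against a resistive circuit.
- **Gauge pair**: two gauge sensors sampled at 100 Hz, each
  moving-averaged over a window (default 10 samples) before subtraction;
  for white noise the dP variance scales as 1/window. Optional 24-bit
  quantisation over the configured full scale (default 300 mbar).
- **Level sensing**: V = (p_bottom − p_air)·A/(ρg), the exact inverse of
  the head model, so direct sensing is noiseless in the twin. The remote
  (dip-tube) variant adds an offset linear in applied air pressure and in
  the inverse tube cross-section, reproducing the observed
  diameter-dependence (0.8 mm tube worse than 3 mm); its coefficient is
  uncalibrated — only the sign and the area scaling are meaningful.

Noise is Gaussian and every stochastic path is seeded; a run seed fixes
the whole telemetry bit-for-bit.

## Controller

Positional PID at 10 Hz on the damped dP estimate (the 100 Hz stream is
decimated by the averaging window — this *is* the signal dampening), with
commands cmd₁ = p_mid + u/2, cmd₂ = p_mid − u/2, p_mid equal to the P_OoC
setpoint. The decomposition decouples flow from internal pressure: in a
linear circuit, changing the back-pressure target shifts both commands
equally and leaves the steady flow unchanged. Clamping anti-windup freezes
the integral whenever either command saturates; NaN measurements hold the
last command. Default gains kp = 0.5, ki = 0.2 s⁻¹, kd = 0 were tuned on
the single-chip tubing-loop fixture (closed-loop settling ≈30 s, well
inside the 60 s settling exclusion used by the stability checks); gains
must be re-matched when the circuit resistance changes substantially.

Switching is level-based with hysteresis (default: trigger at
switch_low − 0.25 mL) and a 30 s lockout, which bounds chatter to at most
one switch per lockout window under level noise. In graetz mode a switch
swaps the two pressure commands and the bridge keeps the sample
unidirectional; the dP controller's integral is mirrored at the swap so
the loop re-settles symmetrically. In active_valve mode the two 3/2 valves
re-route the sample: a correctly synchronised toggle waits for the circuit
flow to cross zero after the command swap, while the test hook
`valve_lag_ticks` toggles early and exposes the sample to the
not-yet-reversed pressure difference, producing the transient backflow
that motivates the passive bridge.

## Fixtures and problem sizes

The generator emits the bench circuits the twin emulates: a single
moulded chip (1.1 cm × 500 µm × 500 µm, medium at 37 °C, µ = 0.00079 Pa·s),
the water-filled 8 cm / 250 µm tubing loop (≈209 µL/min at 29 mbar), the
four-valve Graetz bridge, the 4-slot × 3-channel circuit board with
dummy-chip blanking, and a full system. FCB feeder/waste segments default
to 1 mm × 1 mm milled channels at 15 mm pitch — fixture values standing in
for board drawings that are not reproduced here, and the reason the
board's parallel speed-up is below the ideal channel count.

Long-horizon behaviour is validated on scaled-down runs — 10 simulated
minutes for setpoint stability and 30 simulated minutes for recirculating
volume conservation at dt = 0.01 s — chosen as the shortest horizons that
include settling, head drift and multiple direction switches.

## What the twin does and does not show

Passing tests demonstrate the *mechanisms*: rectified recirculation,
head-drift decay, the fouling failure mode, dP/P_OoC decoupling, and
level-based switching that never drains a reservoir. They do not certify
hardware magnitudes the model does not carry: fouled-sensor calibration
curves, pneumatic overshoot amplitudes, fabrication-tolerance deviations
of the multiplexed board, remote-level offset coefficients, or any
cell-biology quantity (wall shear stress is deliberately out of scope).
PDMS compliance, air compressibility and inertial transients are not
modelled; the quasi-static assumption is good for the second-and-slower
dynamics controlled here.
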