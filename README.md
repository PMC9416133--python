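# perfusim

A desk-scale digital twin of a pressure-driven, recirculating perfusion rig
for organ-on-chip (OoC) devices. It is written for microfluidics engineers
and OoC lab developers who want to size fluidic circuits, predict flow
distribution across multiplexed samples, and exercise the control software
of a pressure-driven perfusion bench — before (or instead of) plumbing the
real thing.

## What it models

**Hydraulics.** Steady laminar flow obeys the fluidic Ohm's law
ΔP = Q·R_h. Element resistances come from the Hagen–Poiseuille formulas

- rectangular channel: R_h ≈ 12µL / (w·h³·(1 − 0.63·min(w,h)/max(w,h)))
- circular tube: R_h = 128µL / (πd⁴)

and arbitrary circuits of channels, tubes, lumped resistors and passive
check valves between pressure terminals are solved by nodal analysis (the
electrical-circuit analogy), with the series law R = ΣR_i and the parallel
law 1/R = Σ1/R_i available for hand reductions. Check valves are ideal
diodes with configurable cracking pressure, resolved by a deterministic
active-set iteration — enough to solve the four-valve **Graetz bridge**
that keeps sample flow unidirectional while the reservoir-side flow
alternates.

**Plant.** Two pressurised 15 mL reservoirs exchange liquid through the
circuit. The hydrostatic head ρgh falls in the donor and rises in the
receiver (≈1.3 mbar of driving pressure lost per displaced mL for 14 mm
tubes), and the pneumatic controllers respond as first-order lags that vent
more slowly than they pressurise.

**Sensors.** Thermal flow sensors with range clipping and medium fouling
(a fouled sensor under-reads, so fixed-flow-rate feedback silently
overdrives the true flow); paired gauge pressure sensors whose damped
difference estimates dP; liquid level from the pressure head, directly or
through a dip tube.

**Controller.** A positional PID holds the dP setpoint while the mean
command tracks the sample back-pressure target (cmd₁,₂ = p_mid ± u/2), with
clamping anti-windup, level-based recirculation switching with hysteresis
and lockout, per-sequence summaries and a notification hook.

## Worked example

```
$ perfusim fixtures --out fx
$ perfusim predict --circuit fx/tubing_loop_48h.json --dp 29
element             flow_ulmin
sample                 208.526
TOTAL                  208.526
```

29 mbar across 8 cm of 250 µm ID tubing filled with water drives
≈209 µL/min — the "about 200 µL/min" operating point of a long-term
single-chip perfusion. Closed loop:

```
$ perfusim simulate --config fx/tubing_loop_48h_config.json --minutes 10 --out tel.csv --seed 1
telemetry: tel.csv (6000 rows)
summaries: tel.summaries.jsonl (1 sequences)
```

After the 60 s settling transient the telemetry shows mean dP 28.98 mbar
and mean true flow 208.4 µL/min: the controller holds the pressure
difference (and hence the flow) against sensor noise and the slow head
drift as volume moves between reservoirs.

The same library objects are importable directly
(`perfusim.solve_network`, `perfusim.run_experiment`, …) for scripted
studies such as FCB blockage analyses or fouling failure-mode sweeps.

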