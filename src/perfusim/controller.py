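"""PID pressure-difference control and recirculation switching.

The control objective mirrors the instrument software this package models:
hold a constant pressure difference (dP) across the samples — which fixes
the flow rate through a linear circuit — while independently setting the
mean sample pressure (P_OoC) through the back pressure of the receiving
reservoir. The actuator commands decompose as

    cmd_hi = p_mid + u/2,   cmd_lo = p_mid − u/2

where ``u`` is the PID output tracking the dP setpoint and ``p_mid`` the
P_OoC target, so dP and P_OoC are decoupled: raising P_OoC raises both
commands equally and leaves the flow unchanged.

Recirculation reverses the reservoir roles before the donor runs dry. The
switch trigger is *level-based* (hydrostatic-head sensing), deliberately not
the displaced volume integrated from the flow sensor — a fouled flow sensor
under-reads and lets reservoirs empty. In ``graetz`` mode the four-valve
bridge rectifies the sample flow so a switch is nothing more than swapping
the two pressure commands; ``active_valve`` mode must toggle two 3/2 valves
in the same control tick, and any desynchronisation shows up as transient
backflow through the sample.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .circuit import FluidicNetwork
from .plant import Plant
from .sensors import FlowSensorModel, GaugePressurePair, LevelSensor, level_from_pressure
from .units import m3_to_ml, m3s_to_ulmin, mbar_to_pa, pa_to_mbar

__all__ = [
    "PIDGains",
    "ControllerConfig",
    "PIDState",
    "SequenceSummary",
    "ExperimentResult",
    "pid_update",
    "should_switch",
    "execute_switch",
    "run_experiment",
]

TELEMETRY_COLUMNS = [
    "time_s",
    "p_inlet_mbar",
    "p_outlet_mbar",
    "dp_mbar",
    "q_true_ulmin",
    "q_measured_ulmin",
    "level1_ml",
    "level2_ml",
    "cmd1_mbar",
    "cmd2_mbar",
    "direction",
]


@dataclass
class PIDGains:
    """PID gains in mbar of command per mbar of dP error (·s for ki, /s for kd).

    Not instrument constants: they must be matched to the hydraulic circuit,
    and the defaults are tuned for the single-chip tubing-loop fixture.
    """

    kp: float = 0.5
    ki: float = 0.2
    kd: float = 0.0

    def __post_init__(self):
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("gains must be >= 0")


@dataclass
class ControllerConfig:
    """Setpoints, mode and switching thresholds. Pressures in mbar, volumes in mL."""

    dp_setpoint: float = 29.0
    p_ooc_setpoint: float = 50.0
    mode: str = "single_pass"  # graetz | active_valve | single_pass
    gains: PIDGains = field(default_factory=PIDGains)
    switch_low_volume: float = 2.0
    switch_high_volume: float = 9.0
    hysteresis: float = 0.25
    switch_lockout_s: float = 30.0
    command_limits: tuple[float, float] = (0.0, 345.0)
    loop_rate: float = 10.0
    sensor_rate: float = 100.0
    sample_element_id: str | None = None

    def __post_init__(self):
        if self.mode not in ("graetz", "active_valve", "single_pass"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.switch_low_volume >= self.switch_high_volume:
            raise ValueError("switch_low_volume must be < switch_high_volume")
        lo, hi = self.command_limits
        if not lo <= self.dp_setpoint <= hi or not lo <= self.p_ooc_setpoint <= hi:
            raise ValueError("setpoints must lie within command limits")


@dataclass
class PIDState:
    integral: float = 0.0
    previous_error: float | None = None
    anti_windup_active: bool = False
    last_commands: tuple[float, float] = (0.0, 0.0)


def pid_update(
    state: PIDState,
    config: ControllerConfig,
    measured_dp: float,
    measured_mean_p: float,
    dt: float,
    direction: int = 1,
) -> tuple[float, float]:
    """One positional-PID step; returns clamped (cmd1, cmd2) in mbar.

    ``measured_dp`` is the damped sensor-1 − sensor-2 difference;
    ``direction`` (+1 reservoir 1 → 2, −1 reversed) orients the setpoint so
    the same loop serves both recirculation half-cycles. The integral is
    frozen whenever either command saturates (clamping anti-windup). A NaN
    measurement holds the last commands and flags the state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if math.isnan(measured_dp) or math.isnan(measured_mean_p):
        state.anti_windup_active = True
        return state.last_commands

    g = config.gains
    error = direction * config.dp_setpoint - measured_dp
    d_term = 0.0
    if g.kd > 0 and state.previous_error is not None:
        d_term = g.kd * (error - state.previous_error) / dt

    trial_integral = state.integral + error * dt
    u = g.kp * error + g.ki * trial_integral + d_term
    p_mid = config.p_ooc_setpoint

    lo, hi = config.command_limits
    raw1, raw2 = p_mid + u / 2.0, p_mid - u / 2.0
    cmd1 = min(max(raw1, lo), hi)
    cmd2 = min(max(raw2, lo), hi)
    saturated = (cmd1 != raw1) or (cmd2 != raw2)
    if not saturated:
        state.integral = trial_integral
    state.anti_windup_active = saturated
    state.previous_error = error
    state.last_commands = (cmd1, cmd2)
    return cmd1, cmd2


def should_switch(
    levels_ml: tuple[float, float],
    config: ControllerConfig,
    current_direction: int,
    time_since_switch: float = math.inf,
    readings_fresh: bool = True,
) -> bool:
    """Decide whether to reverse the recirculation direction.

    True when the donor reservoir has drained to ``switch_low_volume``
    (minus the hysteresis band, so noise at the threshold cannot chatter),
    unless still inside the post-switch lockout. Stale level readings give a
    conservative False.
    """
    if not readings_fresh:
        warnings.warn("stale level readings: holding direction", stacklevel=2)
        return False
    if time_since_switch < config.switch_lockout_s:
        return False
    donor = levels_ml[0] if current_direction > 0 else levels_ml[1]
    return donor <= config.switch_low_volume - config.hysteresis


def execute_switch(
    mode: str,
    commands: tuple[float, float],
    direction: int,
    valve_positions: tuple[bool, bool] | None = None,
) -> tuple[tuple[float, float], int, tuple[bool, bool] | None]:
    """Reverse the perfusion direction.

    graetz: swap the two pressure commands — the bridge keeps the sample
    unidirectional. active_valve: swap commands *and* toggle both 3/2 valves
    in the same tick. Returns (new commands, new direction, new valves).
    Applying it twice restores the original state.
    """
    cmd1, cmd2 = commands
    new_commands = (cmd2, cmd1)
    new_direction = -direction
    new_valves = valve_positions
    if mode == "active_valve":
        if valve_positions is None:
            valve_positions = (False, False)
        new_valves = (not valve_positions[0], not valve_positions[1])
    elif mode not in ("graetz", "single_pass"):
        raise ValueError(f"unknown mode {mode!r}")
    return new_commands, new_direction, new_valves


@dataclass
class SequenceSummary:
    """Per-direction-sequence report, mirroring the per-switch experiment log."""

    direction: int
    start_s: float
    duration_s: float
    mean_dp_mbar: float
    min_dp_mbar: float
    max_dp_mbar: float
    mean_flow_ulmin: float
    displaced_volume_ml: float
    switch_count: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class ExperimentResult:
    telemetry: pd.DataFrame
    summaries: list[SequenceSummary]
    aborted: str | None = None


def run_experiment(
    plant: Plant,
    config: ControllerConfig,
    duration: float,
    seed: int = 0,
    flow_sensor: FlowSensorModel | None = None,
    gauge_pair: GaugePressurePair | None = None,
    level_sensors: tuple[LevelSensor, LevelSensor] | None = None,
    notification_hook: Callable[[SequenceSummary], None] | None = None,
    valve_lag_ticks: int = 0,
) -> ExperimentResult:
    """Closed-loop simulation of a controlled (re)circulating perfusion run.

    The plant is stepped at the sensor rate (default 100 Hz); the PID runs at
    ``config.loop_rate`` on the damped pressure readings, which decimates the
    sensor stream by averaging. Telemetry rows are emitted at the control
    rate. A per-sequence summary is produced at every direction switch and at
    the end of the run; ``notification_hook`` is invoked with each summary
    (a stand-in for the experiment-monitoring e-mail, no-op by default).

    ``valve_lag_ticks`` (active_valve mode only) delays the valve toggle
    behind the command swap by that many control ticks — a test hook for the
    backflow caused by desynchronised switching.

    All stochastic sensor models are seeded from ``seed``; a repeated call
    with the same arguments yields identical telemetry. A drained donor
    reservoir aborts the run with a diagnostic in ``result.aborted``.
    """
    rng = np.random.default_rng(seed)
    if flow_sensor is None:
        flow_sensor = FlowSensorModel(seed=int(rng.integers(2**31)))
    if gauge_pair is None:
        gauge_pair = GaugePressurePair(noise_sd=5.0, seed=int(rng.integers(2**31)))
    if level_sensors is None:
        level_sensors = (LevelSensor("direct"), LevelSensor("direct"))

    dt = 1.0 / config.sensor_rate
    decim = max(int(round(config.sensor_rate / config.loop_rate)), 1)
    n_steps = int(round(duration * config.sensor_rate))

    pid = PIDState()
    direction = 1
    valves: tuple[bool, bool] | None = (False, False) if config.mode == "active_valve" else None
    awaiting_crossover = False  # synced toggle waits for the flow zero-crossing
    pending_valve_toggle = -1  # control ticks until a (deliberately early) toggle
    time_since_switch = math.inf
    switch_count = 0
    aborted = None

    rows: list[dict] = []
    seq_rows_start = 0
    seq_start_t = 0.0
    seq_displaced = 0.0
    summaries: list[SequenceSummary] = []

    def close_sequence(t_now: float) -> None:
        nonlocal seq_rows_start, seq_start_t, seq_displaced
        seq = rows[seq_rows_start:]
        if seq:
            dps = [r["dp_mbar"] * r["direction"] for r in seq]
            flows = [r["q_true_ulmin"] for r in seq]
            summary = SequenceSummary(
                direction=direction,
                start_s=seq_start_t,
                duration_s=t_now - seq_start_t,
                mean_dp_mbar=float(np.mean(dps)),
                min_dp_mbar=float(np.min(dps)),
                max_dp_mbar=float(np.max(dps)),
                mean_flow_ulmin=float(np.mean(flows)),
                displaced_volume_ml=m3_to_ml(abs(seq_displaced)),
                switch_count=switch_count,
            )
            summaries.append(summary)
            if notification_hook is not None:
                notification_hook(summary)
        seq_rows_start = len(rows)
        seq_start_t = t_now
        seq_displaced = 0.0

    for k in range(n_steps):
        state = plant.step(dt)
        seq_displaced += state.last_flow * dt
        if state.dry_run:
            aborted = f"dry run: donor reservoir at dead volume at t={state.time:.2f} s"
            break

        r1, r2 = state.reservoirs
        gauge_pair.sample(r1.bottom_pressure, r2.bottom_pressure)

        if (k + 1) % decim != 0:
            continue

        # control tick
        t = state.time
        measured_dp_pa = gauge_pair.read_dp()
        measured_mean_pa = gauge_pair.read_mean()
        head1 = level_sensors[0].read_head(r1.head_pressure, r1.applied_air_pressure)
        head2 = level_sensors[1].read_head(r2.head_pressure, r2.applied_air_pressure)
        level1 = m3_to_ml(level_from_pressure(head1, 0.0, r1.density, r1.cross_section_area))
        level2 = m3_to_ml(level_from_pressure(head2, 0.0, r2.density, r2.cross_section_area))

        time_since_switch += decim * dt
        do_switch = config.mode != "single_pass" and should_switch(
            (level1, level2), config, direction, time_since_switch
        )
        if do_switch:
            close_sequence(t)
            _, direction, _ = execute_switch(config.mode, pid.last_commands, direction, valves)
            if config.mode == "active_valve":
                # a well-synchronised toggle waits for the circuit flow to
                # cross zero; the lag hook toggles early, exposing the sample
                # to the not-yet-reversed pressure difference
                if valve_lag_ticks > 0:
                    pending_valve_toggle = valve_lag_ticks
                else:
                    awaiting_crossover = True
            # mirror the integral so the loop re-settles symmetrically
            pid.integral = -pid.integral
            pid.previous_error = None
            time_since_switch = 0.0
            switch_count += 1
        if pending_valve_toggle > 0:
            pending_valve_toggle -= 1
            if pending_valve_toggle == 0:
                valves = (not valves[0], not valves[1])
        elif awaiting_crossover and plant.state.last_flow * direction >= 0:
            valves = (not valves[0], not valves[1])
            awaiting_crossover = False

        cmd1, cmd2 = pid_update(
            pid,
            config,
            pa_to_mbar(measured_dp_pa),
            pa_to_mbar(measured_mean_pa),
            decim * dt,
            direction,
        )
        state.pneumatics[0].set_command(mbar_to_pa(cmd1))
        state.pneumatics[1].set_command(mbar_to_pa(cmd2))

        sol = plant.last_solution
        if config.sample_element_id is not None and sol is not None:
            q_sample = sol.element_flows[config.sample_element_id]
        else:
            q_sample = state.last_flow
        if config.mode == "active_valve" and valves is not None:
            # the 3/2 valves re-route the sample: with toggled routing the
            # sample sees the circuit flow in its opposite orientation, so
            # a valve toggle lagging the command swap shows up as backflow
            q_sample = -q_sample if valves[0] else q_sample
        q_true_ulmin = m3s_to_ulmin(q_sample)
        q_meas = flow_sensor.read(q_true_ulmin, t)

        rows.append(
            {
                "time_s": t,
                "p_inlet_mbar": pa_to_mbar(gauge_pair.damped_inlet),
                "p_outlet_mbar": pa_to_mbar(gauge_pair.damped_outlet),
                "dp_mbar": pa_to_mbar(measured_dp_pa),
                "q_true_ulmin": q_true_ulmin,
                "q_measured_ulmin": q_meas,
                "level1_ml": level1,
                "level2_ml": level2,
                "cmd1_mbar": cmd1,
                "cmd2_mbar": cmd2,
                "direction": direction,
            }
        )

    close_sequence(plant.state.time)
    telemetry = pd.DataFrame(rows, columns=TELEMETRY_COLUMNS)
    return ExperimentResult(telemetry=telemetry, summaries=summaries, aborted=aborted)
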