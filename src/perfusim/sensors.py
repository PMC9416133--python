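"""Models of the measurement chain.

Three instruments matter to the control loop and each fails in its own way:

* **Thermal flow sensors** read the mass flow from a temperature gradient.
  Protein and debris deposition from culture medium ("fouling") degrades
  their calibration so a fouled sensor *under-reads* the true flow — which,
  under fixed-flow-rate feedback, silently drives the true flow far above
  the setpoint. Readings also saturate at the sensor's range.
* **Gauge pressure sensor pairs** stand in for an unavailable wet/wet
  differential sensor: the pressure difference is computed from two separate
  gauge sensors whose 100 Hz streams are dampened (moving-average) before
  subtraction to keep the dP estimate usable.
* **Liquid-level sensing** exploits the hydrostatic head: the difference
  between the pressure at the reservoir bottom and the air pressure above
  the liquid gives the column height, hence the stored volume. A remote
  variant senses through a dip tube and picks up a pressurisation-dependent
  offset that shrinks with tube diameter.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .circuit import branch_flow
from .units import G, m3s_to_ulmin, ulmin_to_m3s

__all__ = [
    "FlowSensorModel",
    "FLOW_SENSOR_L_RANGE",
    "FLOW_SENSOR_XL_RANGE",
    "GaugePressurePair",
    "LevelSensor",
    "read_flow",
    "closed_loop_flow_bias",
    "simulate_fixed_flow_mode",
    "level_from_pressure",
    "remote_level_reading",
]

#: Measurement ranges in µL/min for the two commercial sensor sizes.
FLOW_SENSOR_L_RANGE = (-1100.0, 1000.0)
FLOW_SENSOR_XL_RANGE = (-5500.0, 5500.0)


@dataclass
class FlowSensorModel:
    """Thermal flow sensor with fouling, additive noise and range clipping.

    ``fouling_gain`` is the multiplicative calibration loss: 1 is a clean
    sensor, smaller values under-read proportionally. The fouling law of a
    real sensor is not characterised; a constant gain captures the endpoint
    behaviour that matters for control. Units are µL/min throughout.
    """

    range: tuple[float, float] = FLOW_SENSOR_L_RANGE
    fouling_gain: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fouling_gain <= 1.0:
            raise ValueError("fouling_gain must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._rng = np.random.default_rng(self.seed)

    def read(self, true_q_ulmin: float, t: float = 0.0) -> float:
        return read_flow(self, true_q_ulmin, t)


def read_flow(model: FlowSensorModel, true_q_ulmin: float, t: float = 0.0) -> float:
    """Measured flow in µL/min: clip(gain × true + noise, range)."""
    noise = model._rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    lo, hi = model.range
    return float(np.clip(model.fouling_gain * true_q_ulmin + noise, lo, hi))


def closed_loop_flow_bias(
    fouling_gain: float,
    setpoint_ulmin: float,
    circuit_resistance: float | None = None,
    max_pressure_pa: float = 34_500.0,
) -> tuple[float, bool]:
    """True steady flow when fixed-flow-rate feedback trusts a fouled sensor.

    The loop raises pressure until the *measured* flow equals the setpoint,
    so the true flow settles at setpoint / fouling_gain — a gain of 0.25
    quadruples the real perfusion rate. If ``circuit_resistance`` (Pa·s/m³)
    is given, the pressure needed for that true flow is checked against the
    controller range and a saturation flag is returned; a saturated loop
    instead delivers max_pressure / resistance.

    Returns ``(true_flow_ulmin, saturated)``.
    """
    if not 0.0 < fouling_gain <= 1.0:
        raise ValueError("fouling_gain must be in (0, 1]")
    true_q = setpoint_ulmin / fouling_gain
    saturated = False
    if circuit_resistance is not None:
        required = ulmin_to_m3s(true_q) * circuit_resistance
        if required > max_pressure_pa:
            saturated = True
            true_q = m3s_to_ulmin(max_pressure_pa / circuit_resistance)
    return true_q, saturated


def simulate_fixed_flow_mode(
    fouling_gain: float,
    setpoint_ulmin: float,
    circuit_resistance: float,
    max_pressure_pa: float = 34_500.0,
    ki: float = 2.0,
    duration: float = 300.0,
    dt: float = 0.05,
) -> tuple[float, bool]:
    """Run the fixed-flow-rate failure mode as an actual feedback loop.

    An integral controller adjusts the applied pressure so the fouled
    sensor's reading tracks the setpoint, against a purely resistive
    circuit. Returns the final *true* flow in µL/min and a saturation flag.
    ``ki`` is in Pa per (µL/min of error) per second.
    """
    sensor = FlowSensorModel(FLOW_SENSOR_XL_RANGE, fouling_gain=fouling_gain)
    pressure = 0.0
    true_q = 0.0
    for _ in range(int(duration / dt)):
        true_q = m3s_to_ulmin(branch_flow(pressure, circuit_resistance))
        measured = sensor.read(true_q)
        pressure += ki * (setpoint_ulmin - measured) * dt
        pressure = min(max(pressure, 0.0), max_pressure_pa)
    return true_q, pressure >= max_pressure_pa - 1e-9


@dataclass
class GaugePressurePair:
    """Two gauge pressure sensors whose damped difference estimates dP.

    Each sensor stream (default 100 Hz) is moving-averaged over
    ``dampening_window`` samples before subtraction; for white noise this
    cuts the variance of the dP estimate by the window length. Optional
    24-bit quantisation over ``full_scale_pa`` models the ADC.
    """

    offset_inlet: float = 0.0
    offset_outlet: float = 0.0
    noise_sd: float = 0.0
    sample_rate: float = 100.0
    dampening_window: int = 10
    full_scale_pa: float = 30_000.0
    quantize: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.dampening_window < 1:
            raise ValueError("dampening_window must be >= 1")
        self._rng = np.random.default_rng(self.seed)
        self._buf_in: deque = deque(maxlen=self.dampening_window)
        self._buf_out: deque = deque(maxlen=self.dampening_window)

    def _measure(self, true_p: float, offset: float) -> float:
        p = true_p + offset
        if self.noise_sd > 0:
            p += self._rng.normal(0.0, self.noise_sd)
        if self.quantize:
            lsb = self.full_scale_pa / (2**24 - 1)
            p = round(p / lsb) * lsb
        return p

    def sample(self, true_inlet: float, true_outlet: float) -> None:
        """Ingest one 100 Hz sample pair (pressures in Pa)."""
        self._buf_in.append(self._measure(true_inlet, self.offset_inlet))
        self._buf_out.append(self._measure(true_outlet, self.offset_outlet))

    @property
    def damped_inlet(self) -> float:
        if not self._buf_in:
            raise RuntimeError("no samples ingested")
        return sum(self._buf_in) / len(self._buf_in)

    @property
    def damped_outlet(self) -> float:
        if not self._buf_out:
            raise RuntimeError("no samples ingested")
        return sum(self._buf_out) / len(self._buf_out)

    def read_dp(self) -> float:
        """Damped pressure difference inlet − outlet, Pa."""
        return self.damped_inlet - self.damped_outlet

    def read_mean(self) -> float:
        """Damped mean of the two sensors, Pa (proxy for sample pressure)."""
        return 0.5 * (self.damped_inlet + self.damped_outlet)


@dataclass
class LevelSensor:
    """Reservoir liquid-level sensor based on hydrostatic head.

    ``direct`` mode is a sensor sealed into the reservoir bottom and reads
    the head exactly. ``remote`` mode senses through a dip tube from the
    cap; pressurising the reservoir forces liquid into the tube and adds a
    spurious offset proportional to the applied air pressure and to the
    inverse tube cross-section (wider tubes suffer less). The offset
    coefficient is phenomenological, not calibrated against hardware.
    """

    mode: str = "direct"
    tube_diameter: float = 0.003
    pressurization_offset_coeff: float = 1e-9  # Pa per Pa applied, per m² of tube area

    def __post_init__(self):
        if self.mode not in ("direct", "remote"):
            raise ValueError("mode must be 'direct' or 'remote'")
        if self.mode == "remote" and self.tube_diameter <= 0:
            raise ValueError("tube_diameter must be > 0 in remote mode")

    def read_head(self, true_head: float, applied_air: float = 0.0) -> float:
        return remote_level_reading(self, true_head, applied_air)


def level_from_pressure(p_bottom: float, p_air: float, rho: float, area: float) -> float:
    """Stored liquid volume (m³) from a bottom/air pressure pair.

    Inverts the hydrostatic relation: V = (p_bottom − p_air)·A / (ρg). A
    negative head is physically impossible for a submerged sensor and is
    flagged (sensor above the liquid, or an air pocket).
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    head = p_bottom - p_air
    if head < 0:
        raise ValueError("negative pressure head: sensor above liquid or bubble present")
    return head / (rho * G) * area


def remote_level_reading(sensor: LevelSensor, true_head: float, applied_air: float = 0.0) -> float:
    """Measured head in Pa, including the remote-tube pressurisation offset."""
    if sensor.mode == "direct":
        return true_head
    area = math.pi * sensor.tube_diameter**2 / 4.0
    return true_head + sensor.pressurization_offset_coeff * applied_air / area
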