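"""Configuration and circuit files.

Circuits and run configurations are JSON (YAML is accepted on load); all
human-facing quantities carry explicit unit suffixes (``_mm``, ``_um``,
``_mbar``, ``_ml``, ``_ulmin``) and are converted to SI at the boundary.
Unknown keys are rejected by name, so a typo fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .circuit import (
    CheckValve,
    CircularTube,
    FixedResistor,
    FluidProperties,
    FluidicNetwork,
    NetworkElement,
    RectangularChannel,
)
from .controller import ControllerConfig, PIDGains
from .plant import Plant, PneumaticChannel, Reservoir
from .sensors import FlowSensorModel, GaugePressurePair

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_circuit",
    "save_circuit",
    "load_config",
    "generate_fixtures",
]


class ConfigError(ValueError):
    """A configuration file violates the schema; the message names the key."""


def _check_keys(obj: dict, allowed: set[str], context: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")


def _require(obj: dict, key: str, context: str):
    if key not in obj:
        raise ConfigError(f"missing key {key!r} in {context}")
    return obj[key]


def _read(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return data


# ---------------------------------------------------------------------------
# circuits

_ELEMENT_KEYS = {
    "rect": {"length_mm", "width_um", "height_um"},
    "tube": {"length_mm", "diameter_um"},
    "resistor": {"resistance_pa_s_per_m3"},
    "check_valve": {"cracking_pressure_mbar", "forward_resistance_pa_s_per_m3"},
}


def _parse_element(entry: dict, i: int):
    context = f"elements[{i}]"
    kind = _require(entry, "kind", context)
    if kind not in _ELEMENT_KEYS:
        raise ConfigError(f"unknown element kind {kind!r} in {context}")
    _check_keys(entry, {"id", "kind", "from", "to"} | _ELEMENT_KEYS[kind], context)
    if kind == "rect":
        el = RectangularChannel(
            _require(entry, "length_mm", context) / 1000.0,
            _require(entry, "width_um", context) / 1e6,
            _require(entry, "height_um", context) / 1e6,
        )
    elif kind == "tube":
        el = CircularTube(
            _require(entry, "length_mm", context) / 1000.0,
            _require(entry, "diameter_um", context) / 1e6,
        )
    elif kind == "resistor":
        el = FixedResistor(_require(entry, "resistance_pa_s_per_m3", context))
    else:
        fr = entry.get("forward_resistance_pa_s_per_m3")
        el = CheckValve(entry.get("cracking_pressure_mbar", 0.0) * 100.0, fr)
    return NetworkElement(
        entry.get("id", f"el_{i}"),
        el,
        _require(entry, "from", context),
        _require(entry, "to", context),
    )


def load_circuit(path: str | Path) -> FluidicNetwork:
    """Load and validate a circuit description (JSON or YAML)."""
    data = _read(path)
    _check_keys(data, {"fluid", "terminals", "elements"}, str(path))
    fl = _require(data, "fluid", str(path))
    _check_keys(fl, {"viscosity_pa_s", "density_kg_m3", "label"}, "fluid")
    fluid = FluidProperties(
        _require(fl, "viscosity_pa_s", "fluid"),
        fl.get("density_kg_m3", 1000.0),
        fl.get("label", ""),
    )
    terminals = {
        node: mbar * 100.0 for node, mbar in _require(data, "terminals", str(path)).items()
    }
    elements = [_parse_element(e, i) for i, e in enumerate(_require(data, "elements", str(path)))]
    net = FluidicNetwork(elements, terminals, fluid)
    net.validate()
    return net


def _element_to_dict(el: NetworkElement) -> dict:
    d: dict = {"id": el.id}
    obj = el.element
    if isinstance(obj, RectangularChannel):
        d |= {
            "kind": "rect",
            "length_mm": obj.length * 1000.0,
            "width_um": obj.width * 1e6,
            "height_um": obj.height * 1e6,
        }
    elif isinstance(obj, CircularTube):
        d |= {"kind": "tube", "length_mm": obj.length * 1000.0, "diameter_um": obj.diameter * 1e6}
    elif isinstance(obj, FixedResistor):
        d |= {"kind": "resistor", "resistance_pa_s_per_m3": obj.resistance_value}
    elif isinstance(obj, CheckValve):
        d |= {
            "kind": "check_valve",
            "cracking_pressure_mbar": obj.cracking_pressure / 100.0,
            "forward_resistance_pa_s_per_m3": obj.forward_resistance,
        }
    d |= {"from": el.node_from, "to": el.node_to}
    return d


def save_circuit(net: FluidicNetwork, path: str | Path) -> None:
    data = {
        "fluid": {
            "viscosity_pa_s": net.fluid.dynamic_viscosity,
            "density_kg_m3": net.fluid.density,
            "label": net.fluid.label,
        },
        "terminals": {node: p / 100.0 for node, p in net.terminals.items()},
        "elements": [_element_to_dict(el) for el in net.elements],
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


# ---------------------------------------------------------------------------
# run configuration

_CONTROLLER_KEYS = {
    "dp_setpoint_mbar",
    "p_ooc_setpoint_mbar",
    "mode",
    "gains",
    "switch_low_ml",
    "switch_high_ml",
    "hysteresis_ml",
    "switch_lockout_s",
    "loop_rate_hz",
    "sample_element_id",
}
_PLANT_KEYS = {
    "reservoir_diameter_mm",
    "initial_volumes_ml",
    "dead_volume_ml",
    "density_kg_m3",
    "pressurize_tau_s",
    "vent_tau_1_s",
    "vent_tau_2_s",
}
_SENSOR_KEYS = {
    "flow_range_ulmin",
    "fouling_gain",
    "flow_noise_sd_ulmin",
    "pressure_noise_sd_mbar",
    "dampening_window",
}


@dataclass
class RunConfig:
    """Fully validated simulation configuration with factory helpers."""

    circuit_path: Path
    seed: int = 0
    controller: dict = field(default_factory=dict)
    plant: dict = field(default_factory=dict)
    sensors: dict = field(default_factory=dict)

    def build_network(self) -> FluidicNetwork:
        return load_circuit(self.circuit_path)

    def build_controller_config(self) -> ControllerConfig:
        c = self.controller
        gains = PIDGains(**c.get("gains", {}))
        return ControllerConfig(
            dp_setpoint=c.get("dp_setpoint_mbar", 29.0),
            p_ooc_setpoint=c.get("p_ooc_setpoint_mbar", 50.0),
            mode=c.get("mode", "single_pass"),
            gains=gains,
            switch_low_volume=c.get("switch_low_ml", 2.0),
            switch_high_volume=c.get("switch_high_ml", 9.0),
            hysteresis=c.get("hysteresis_ml", 0.25),
            switch_lockout_s=c.get("switch_lockout_s", 30.0),
            loop_rate=c.get("loop_rate_hz", 10.0),
            sample_element_id=c.get("sample_element_id"),
        )

    def build_plant(self, net: FluidicNetwork | None = None) -> Plant:
        p = self.plant
        if net is None:
            net = self.build_network()
        rho = p.get("density_kg_m3", net.fluid.density)
        d = p.get("reservoir_diameter_mm", 14.0) / 1000.0
        vols = p.get("initial_volumes_ml", [10.0, 3.0])
        dead = p.get("dead_volume_ml", 1.0)
        reservoirs = tuple(
            Reservoir(
                inner_diameter=d,
                liquid_volume=v * 1e-6,
                dead_volume=dead * 1e-6,
                density=rho,
            )
            for v in vols
        )
        tau_p = p.get("pressurize_tau_s", 0.3)
        pneumatics = (
            PneumaticChannel(pressurize_time_constant=tau_p, vent_time_constant=p.get("vent_tau_1_s", 2.0)),
            PneumaticChannel(pressurize_time_constant=tau_p, vent_time_constant=p.get("vent_tau_2_s", 1.0)),
        )
        terms = tuple(net.terminals)
        return Plant(net, reservoirs, pneumatics, terminal_order=(terms[0], terms[1]))

    def build_flow_sensor(self, seed: int) -> FlowSensorModel:
        s = self.sensors
        return FlowSensorModel(
            range=tuple(s.get("flow_range_ulmin", (-1100.0, 1000.0))),
            fouling_gain=s.get("fouling_gain", 1.0),
            noise_sd=s.get("flow_noise_sd_ulmin", 0.0),
            seed=seed,
        )

    def build_gauge_pair(self, seed: int) -> GaugePressurePair:
        s = self.sensors
        return GaugePressurePair(
            noise_sd=s.get("pressure_noise_sd_mbar", 0.05) * 100.0,
            dampening_window=s.get("dampening_window", 10),
            seed=seed,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration; defaults fill absent keys."""
    path = Path(path)
    data = _read(path)
    _check_keys(data, {"circuit", "seed", "controller", "plant", "sensors"}, str(path))
    circuit_rel = _require(data, "circuit", str(path))
    circuit_path = (path.parent / circuit_rel).resolve()
    if not circuit_path.exists():
        raise ConfigError(f"circuit file {circuit_rel!r} referenced by {path} does not exist")
    controller = data.get("controller", {})
    _check_keys(controller, _CONTROLLER_KEYS, "controller")
    if "gains" in controller:
        _check_keys(controller["gains"], {"kp", "ki", "kd"}, "controller.gains")
    plant = data.get("plant", {})
    _check_keys(plant, _PLANT_KEYS, "plant")
    sensors = data.get("sensors", {})
    _check_keys(sensors, _SENSOR_KEYS, "sensors")
    cfg = RunConfig(
        circuit_path=circuit_path,
        seed=int(data.get("seed", 0)),
        controller=controller,
        plant=plant,
        sensors=sensors,
    )
    cfg.build_controller_config()  # validate eagerly
    return cfg


# ---------------------------------------------------------------------------
# fixtures

def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the standard bench circuits and a matching run config.

    Emits ``single_chip``, ``tubing_loop_48h``, ``fcb_6ch``, ``fcb_12ch``,
    ``graetz_bridge`` and ``full_system`` circuit files plus
    ``tubing_loop_48h_config.json``; returns the written paths.
    """
    from . import fixtures as fx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    circuits = {
        "single_chip": fx.single_chip_network(),
        "tubing_loop_48h": fx.tubing_loop_network(),
        "fcb_6ch": fx.fcb_network(6),
        "fcb_12ch": fx.fcb_network(12),
        "graetz_bridge": fx.graetz_bridge_network(),
        "full_system": fx.full_system_network(),
    }
    for name, net in circuits.items():
        p = out / f"{name}.json"
        save_circuit(net, p)
        written.append(p)
    config = {
        "circuit": "tubing_loop_48h.json",
        "seed": 1,
        "controller": {
            "dp_setpoint_mbar": 29.0,
            "p_ooc_setpoint_mbar": 50.0,
            "mode": "single_pass",
            "sample_element_id": "sample",
        },
        "plant": {"initial_volumes_ml": [10.0, 3.0]},
        "sensors": {"pressure_noise_sd_mbar": 0.05, "dampening_window": 10},
    }
    p = out / "tubing_loop_48h_config.json"
    p.write_text(json.dumps(config, indent=1) + "\n")
    written.append(p)
    return written
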