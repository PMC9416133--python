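"""Builders for the bench circuits the digital twin emulates.

Each function returns a ready-to-solve :class:`FluidicNetwork` between the
terminal nodes ``res1`` and ``res2`` (the two medium reservoirs, both at
0 Pa until a solve or a plant imposes pressures):

* ``single_chip`` — one moulded PDMS chip (1.1 cm × 500 µm × 500 µm) in
  culture medium.
* ``tubing_loop`` — the long-term validation circuit: an 8 cm length of
  250 µm ID tubing perfused with water; at a 29 mbar pressure difference it
  carries roughly 200 µL/min.
* ``graetz_bridge`` — four check valves in bridge orientation around a
  sample branch, so the sample flow stays unidirectional whichever
  reservoir is pressurised.
* ``fcb`` boards — see :mod:`perfusim.fcb`.
* ``full_system`` — tubing from each reservoir into a Graetz bridge whose
  rectified branch is the single chip.
"""

from __future__ import annotations

from .circuit import (
    CheckValve,
    CircularTube,
    FluidProperties,
    FluidicNetwork,
    MEDIUM_37C,
    NetworkElement,
    RectangularChannel,
    WATER_20C,
)
from .fcb import FCBLayout, build_fcb_network
from .plant import Plant, PneumaticChannel, Reservoir

__all__ = [
    "CHIP_CHANNEL",
    "LOOP_TUBE",
    "single_chip_network",
    "tubing_loop_network",
    "graetz_bridge_network",
    "fcb_network",
    "full_system_network",
    "make_plant",
]

#: PDMS organ-on-chip flow channel, 1.1 cm × 500 µm × 500 µm.
CHIP_CHANNEL = RectangularChannel(0.011, 500e-6, 500e-6)
#: Long-term perfusion loop: 8 cm of 250 µm inner-diameter tubing.
LOOP_TUBE = CircularTube(0.08, 250e-6)


def single_chip_network(fluid: FluidProperties = MEDIUM_37C) -> FluidicNetwork:
    """A single chip directly between the reservoirs."""
    return FluidicNetwork(
        [NetworkElement("sample", CHIP_CHANNEL, "res1", "res2")],
        {"res1": 0.0, "res2": 0.0},
        fluid,
    )


def tubing_loop_network(fluid: FluidProperties = WATER_20C) -> FluidicNetwork:
    """The 48 h validation loop: 8 cm / 250 µm tubing in water."""
    return FluidicNetwork(
        [NetworkElement("sample", LOOP_TUBE, "res1", "res2")],
        {"res1": 0.0, "res2": 0.0},
        fluid,
    )


def _bridge_elements(sample_elements: list[NetworkElement]) -> list[NetworkElement]:
    """Four check valves around the given sample branch (s_in → s_out)."""
    return [
        NetworkElement("valve_1", CheckValve(), "res1", "s_in"),
        NetworkElement("valve_2", CheckValve(), "s_out", "res2"),
        NetworkElement("valve_3", CheckValve(), "res2", "s_in"),
        NetworkElement("valve_4", CheckValve(), "s_out", "res1"),
        *sample_elements,
    ]


def graetz_bridge_network(fluid: FluidProperties = WATER_20C) -> FluidicNetwork:
    """Four-valve bridge rectifying the tubing-loop sample."""
    sample = [NetworkElement("sample", LOOP_TUBE, "s_in", "s_out")]
    return FluidicNetwork(_bridge_elements(sample), {"res1": 0.0, "res2": 0.0}, fluid)


def fcb_network(n_channels: int = 6, fluid: FluidProperties = MEDIUM_37C) -> FluidicNetwork:
    """FCB with the requested number of occupied channels (multiples of 3).

    Six channels is the two-device validation configuration; twelve is the
    fully loaded board. The network spans ``inlet`` → ``outlet``; rename or
    re-terminal as needed.
    """
    if n_channels % 3 != 0 or not 3 <= n_channels <= 12:
        raise ValueError("n_channels must be 3, 6, 9 or 12")
    slots = n_channels // 3
    layout = FCBLayout(occupancy=tuple([True] * slots + [False] * (4 - slots)))
    return build_fcb_network(layout, fluid)


def full_system_network(fluid: FluidProperties = MEDIUM_37C) -> FluidicNetwork:
    """Reservoir tubing feeding a Graetz bridge around the single chip."""
    sample = [
        NetworkElement("feed_tube", CircularTube(0.10, 500e-6), "s_in", "chip_in"),
        NetworkElement("sample", CHIP_CHANNEL, "chip_in", "chip_out"),
        NetworkElement("return_tube", CircularTube(0.10, 500e-6), "chip_out", "s_out"),
    ]
    return FluidicNetwork(_bridge_elements(sample), {"res1": 0.0, "res2": 0.0}, fluid)


def make_plant(
    net: FluidicNetwork,
    initial_volumes_ml: tuple[float, float] = (10.0, 3.0),
    reservoir_diameter: float = 0.014,
    dead_volume_ml: float = 1.0,
    density: float | None = None,
) -> Plant:
    """Standard rig around a circuit: 15 mL reservoirs and asymmetric pneumatics.

    Channel 1's vent time constant (2.0 s) is slower than channel 2's
    (1.0 s), reproducing the asymmetric venting observed between the two
    pressure-controller channels of the real rig.
    """
    rho = density if density is not None else net.fluid.density
    reservoirs = tuple(
        Reservoir(
            inner_diameter=reservoir_diameter,
            liquid_volume=v * 1e-6,
            dead_volume=dead_volume_ml * 1e-6,
            density=rho,
        )
        for v in initial_volumes_ml
    )
    pneumatics = (
        PneumaticChannel(pressurize_time_constant=0.3, vent_time_constant=2.0),
        PneumaticChannel(pressurize_time_constant=0.3, vent_time_constant=1.0),
    )
    return Plant(net, reservoirs, pneumatics, terminal_order=("res1", "res2"))
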