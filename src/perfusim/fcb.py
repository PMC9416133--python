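"""Fluidic circuit board (FCB) topology and multiplexing analyses.

The FCB is a milled manifold that perfuses up to four organ-on-chip devices
(three channels each, twelve channels total) in parallel: a feeder channel
distributes flow from the inlet to per-slot branch points, each occupied
channel runs feeder → sample → waste, and the waste channel collects the
flow to the outlet. Unused ports are blocked with dummy chips, i.e. absent
branches. Under pressure-driven control the dP across the branch points is
held constant, so each sample's flow depends only on its own resistance —
blocking one channel leaves the others essentially untouched, in contrast
to constant-total-flow drive where the remaining channels take up the lost
share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import (
    CircuitSolver,
    FixedResistor,
    FluidProperties,
    FluidicNetwork,
    MEDIUM_37C,
    NetworkElement,
    RectangularChannel,
    series_total,
)
from .units import mbar_to_pa

__all__ = ["FCBLayout", "build_fcb_network", "predict_dp_q_curve", "blockage_analysis"]

#: Default sample channel: the moulded PDMS flow channel, 1.1 cm × 500 µm × 500 µm.
DEFAULT_CHANNEL = RectangularChannel(0.011, 500e-6, 500e-6)


@dataclass
class FCBLayout:
    """Occupancy and lumped geometry of the board.

    ``occupancy`` marks each slot as carrying a device (True) or a dummy
    chip (False); ``channels_per_slot`` channels are perfused per occupied
    slot. Feeder/waste segments default to milled 1 mm × 1 mm square
    channels of 15 mm per slot pitch — fixture values, the board drawings
    are not reproduced here. ``branch_resistance`` lumps the per-channel
    tubing/connector path; ``sensor_resistance`` optionally models the
    inline flow sensor at the inlet.
    """

    n_slots: int = 4
    channels_per_slot: int = 3
    occupancy: tuple[bool, ...] | None = None
    channel: RectangularChannel = DEFAULT_CHANNEL
    segment_length: float = 0.015
    segment_width: float = 0.001
    segment_height: float = 0.001
    branch_resistance: float = 0.0
    sensor_resistance: float = 0.0

    def __post_init__(self):
        if self.occupancy is None:
            self.occupancy = tuple([True] * self.n_slots)
        if len(self.occupancy) != self.n_slots:
            raise ValueError("occupancy length must equal n_slots")

    @property
    def n_channels(self) -> int:
        return self.channels_per_slot * sum(self.occupancy)

    def channel_ids(self) -> list[str]:
        return [
            f"ch_{slot}_{c}"
            for slot in range(self.n_slots)
            if self.occupancy[slot]
            for c in range(self.channels_per_slot)
        ]


def build_fcb_network(layout: FCBLayout, fluid: FluidProperties = MEDIUM_37C) -> FluidicNetwork:
    """Assemble the board as a hydraulic network between ``inlet`` and ``outlet``.

    Feeder segments chain inlet → f0 → f1 → …, waste segments chain
    … → w1 → w0 → outlet; every occupied channel spans its slot's feeder
    node to its waste node. Dummy slots contribute no flow path.
    """
    if layout.n_channels == 0:
        raise ValueError("no occupied channels on the board")
    elements: list[NetworkElement] = []
    seg = RectangularChannel(layout.segment_length, layout.segment_width, layout.segment_height)
    prev_f, prev_w = "inlet", "outlet"
    if layout.sensor_resistance > 0:
        elements.append(
            NetworkElement("flow_sensor", FixedResistor(layout.sensor_resistance), "inlet", "f_in")
        )
        prev_f = "f_in"
    for slot in range(layout.n_slots):
        f_node, w_node = f"f{slot}", f"w{slot}"
        elements.append(NetworkElement(f"feeder_{slot}", seg, prev_f, f_node))
        elements.append(NetworkElement(f"waste_{slot}", seg, w_node, prev_w))
        if layout.occupancy[slot]:
            for c in range(layout.channels_per_slot):
                cid = f"ch_{slot}_{c}"
                if layout.branch_resistance > 0:
                    mid = f"{cid}_mid"
                    elements.append(
                        NetworkElement(
                            f"{cid}_tube", FixedResistor(layout.branch_resistance), f_node, mid
                        )
                    )
                    elements.append(NetworkElement(cid, layout.channel, mid, w_node))
                else:
                    elements.append(NetworkElement(cid, layout.channel, f_node, w_node))
        prev_f, prev_w = f_node, w_node
    return FluidicNetwork(elements, {"inlet": 0.0, "outlet": 0.0}, fluid)


def predict_dp_q_curve(
    net: FluidicNetwork,
    dp_values_mbar: list[float],
    channel_ids: list[str] | None = None,
) -> list[dict]:
    """Solve the board at each dP and return the (linear) dP–Q relation.

    Each entry carries the applied dP, the total inlet flow, and the
    per-channel flows (m³/s). The curve passes through the origin and its
    slope is the reciprocal of the series-parallel reduced resistance.
    """
    if any(dp < 0 for dp in dp_values_mbar):
        raise ValueError("dp values must be >= 0")
    if channel_ids is None:
        channel_ids = [el.id for el in net.elements if el.id.startswith("ch_")]
    solver = CircuitSolver(net)
    curve = []
    for dp in dp_values_mbar:
        sol = solver.solve({"inlet": mbar_to_pa(dp), "outlet": 0.0})
        curve.append(
            {
                "dp_mbar": dp,
                "q_total": sol.terminal_flow(net, "inlet"),
                "per_channel": {cid: sol.element_flows[cid] for cid in channel_ids},
            }
        )
    return curve


def blockage_analysis(
    net: FluidicNetwork,
    blocked_ids: list[str],
    mode: str = "constant_dp",
    dp_mbar: float = 29.0,
) -> dict:
    """Per-channel flows before and after blocking channels.

    ``constant_dp`` re-solves at the same terminal pressure difference — the
    pressure-driven case, where unblocked channels shift only through
    shared feeder/waste resistance. ``constant_total_q`` rescales the
    driving pressure so the total flow is preserved — the positive-
    displacement-pump case, where the remaining channels absorb the blocked
    channel's share and their mechanical stress rises.
    """
    if mode not in ("constant_dp", "constant_total_q"):
        raise ValueError(f"unknown mode {mode!r}")
    channel_ids = [el.id for el in net.elements if el.id.startswith("ch_")]
    unknown = set(blocked_ids) - set(channel_ids)
    if unknown:
        raise ValueError(f"blocked ids not on the board: {sorted(unknown)}")
    if set(blocked_ids) >= set(channel_ids):
        raise ValueError("cannot block every channel")

    dp_pa = mbar_to_pa(dp_mbar)
    before_sol = CircuitSolver(net).solve({"inlet": dp_pa, "outlet": 0.0})
    before = {cid: before_sol.element_flows[cid] for cid in channel_ids}
    q_total_before = before_sol.terminal_flow(net, "inlet")

    blocked = set(blocked_ids)
    remaining_elements = [
        el
        for el in net.elements
        if el.id not in blocked and not any(el.id == f"{b}_tube" for b in blocked)
    ]
    blocked_net = FluidicNetwork(remaining_elements, dict(net.terminals), net.fluid)
    after_sol = CircuitSolver(blocked_net).solve({"inlet": dp_pa, "outlet": 0.0})
    q_total_after = after_sol.terminal_flow(blocked_net, "inlet")
    scale = 1.0
    if mode == "constant_total_q":
        if q_total_after == 0:
            raise ValueError("no flow path left after blocking")
        # linear network: scaling the driving dP rescales every flow equally
        scale = q_total_before / q_total_after
    after = {
        cid: (after_sol.element_flows[cid] * scale if cid not in blocked else 0.0)
        for cid in channel_ids
    }
    return {
        "mode": mode,
        "dp_mbar": dp_mbar,
        "before": before,
        "after": after,
        "q_total_before": q_total_before,
        "q_total_after": q_total_after * scale,
    }
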