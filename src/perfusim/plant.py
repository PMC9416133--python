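"""Time-domain model of the physical perfusion rig.

Two pressurised medium reservoirs drive fluid through the hydraulic circuit.
The simulated physics are the ones that matter for closed-loop control of a
real bench setup:

* the hydrostatic pressure head ρgh of the liquid column, which falls in the
  donor reservoir and rises in the receiver as volume is displaced, eroding
  the effective driving pressure at roughly 1.2–1.5 mbar per displaced mL for
  15 mL tubes;
* first-order pneumatic response of the pressure controllers, with separate
  pressurise and vent time constants (commercial controllers vent through a
  restrictor and are markedly slower releasing pressure than applying it, and
  the two channels need not match);
* quasi-static volume transfer: the circuit is solved at the instantaneous
  terminal pressures each step, and flow moves liquid between reservoirs.

Air-side compressibility and tubing compliance are not modelled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .circuit import CircuitSolver, FluidicNetwork, FlowSolution
from .units import G

__all__ = [
    "Reservoir",
    "PneumaticChannel",
    "PlantState",
    "Plant",
    "DryRunError",
    "head_pressure",
    "head_drift_per_ml",
    "effective_driving_pressure",
]


class DryRunError(RuntimeError):
    """A donor reservoir has been drained to its dead volume."""


@dataclass
class Reservoir:
    """Cylindrical medium reservoir (default: 15 mL centrifuge tube).

    The conical tip of a real tube is folded into ``dead_volume``, the liquid
    below the outlet that can never be perfused. Volumes in m³, diameter in m.
    """

    inner_diameter: float = 0.014
    liquid_volume: float = 10e-6
    dead_volume: float = 1e-6
    density: float = 1000.0
    applied_air_pressure: float = 0.0  # gauge, Pa
    capacity: float = 15e-6

    def __post_init__(self):
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be > 0")
        if self.liquid_volume < 0:
            raise ValueError("liquid_volume must be >= 0")
        if self.liquid_volume > self.capacity:
            raise ValueError("liquid_volume exceeds capacity")

    @property
    def cross_section_area(self) -> float:
        return math.pi * self.inner_diameter**2 / 4.0

    @property
    def head_pressure(self) -> float:
        return head_pressure(self)

    @property
    def bottom_pressure(self) -> float:
        """Gauge pressure at the reservoir bottom: air pressure + liquid head."""
        return self.applied_air_pressure + self.head_pressure


def head_pressure(res: Reservoir) -> float:
    """Hydrostatic head ρ·g·h of the liquid column, Pa.

    The column height is liquid_volume / cross-section for the cylindrical
    approximation, so the head is linear in the stored volume.
    """
    return res.density * G * res.liquid_volume / res.cross_section_area


def head_drift_per_ml(res_pair: tuple[Reservoir, Reservoir]) -> float:
    """Loss of driving pressure per mL displaced between two reservoirs, mbar/mL.

    When fluid moves donor → receiver, the donor's head falls and the
    receiver's rises; both act against the applied air-pressure difference,
    so the combined decay is ρg·(1/A₁ + 1/A₂) per unit volume.
    """
    a, b = res_pair
    pa_per_m3 = a.density * G / a.cross_section_area + b.density * G / b.cross_section_area
    return pa_per_m3 * 1e-6 / 100.0  # per mL, in mbar


@dataclass
class PneumaticChannel:
    """First-order pneumatic lag with asymmetric pressurise/vent response.

    ``command`` is the controller's requested gauge pressure; the delivered
    ``current_pressure`` relaxes toward it exponentially, faster when
    pressurising than when venting.
    """

    command: float = 0.0
    current_pressure: float = 0.0
    pressurize_time_constant: float = 0.3
    vent_time_constant: float = 1.0
    pressure_range: tuple[float, float] = (0.0, 34_500.0)

    def __post_init__(self):
        if self.pressurize_time_constant <= 0 or self.vent_time_constant <= 0:
            raise ValueError("time constants must be > 0")

    def set_command(self, pressure: float) -> None:
        lo, hi = self.pressure_range
        self.command = min(max(pressure, lo), hi)

    def advance(self, dt: float) -> None:
        tau = (
            self.pressurize_time_constant
            if self.command >= self.current_pressure
            else self.vent_time_constant
        )
        # exact discretisation of dp/dt = (cmd - p)/tau
        self.current_pressure += (self.command - self.current_pressure) * (
            1.0 - math.exp(-dt / tau)
        )


@dataclass
class PlantState:
    """Snapshot of the rig at one instant."""

    time: float
    reservoirs: tuple[Reservoir, Reservoir]
    pneumatics: tuple[PneumaticChannel, PneumaticChannel]
    last_flow: float = 0.0  # m³/s through terminal 1, positive reservoir 1 → 2
    dry_run: bool = False


def effective_driving_pressure(state: PlantState) -> float:
    """Pressure difference actually driving flow: (P_air + P_head)₁ − (P_air + P_head)₂."""
    r1, r2 = state.reservoirs
    return r1.bottom_pressure - r2.bottom_pressure


class Plant:
    """The simulated rig: two reservoirs and pneumatics around a circuit.

    The network's two terminal nodes (in ``terminal_order``) are driven by
    the reservoirs' bottom pressures; each :meth:`step` advances pneumatics,
    solves the circuit quasi-statically and transfers the terminal flow
    between reservoirs. Total liquid volume is conserved exactly by
    construction (a single transferred increment is subtracted from one
    reservoir and added to the other).
    """

    def __init__(
        self,
        net: FluidicNetwork,
        reservoirs: tuple[Reservoir, Reservoir] | None = None,
        pneumatics: tuple[PneumaticChannel, PneumaticChannel] | None = None,
        terminal_order: tuple[str, str] | None = None,
    ):
        if terminal_order is None:
            terms = list(net.terminals)
            if len(terms) != 2:
                raise ValueError("plant requires a two-terminal network")
            terminal_order = (terms[0], terms[1])
        self.terminal_order = terminal_order
        self.solver = CircuitSolver(net)
        self.net = net
        self.state = PlantState(
            time=0.0,
            reservoirs=reservoirs or (Reservoir(), Reservoir()),
            pneumatics=pneumatics or (PneumaticChannel(), PneumaticChannel()),
        )
        self.last_solution: FlowSolution | None = None

    @property
    def min_time_constant(self) -> float:
        return min(
            min(p.pressurize_time_constant, p.vent_time_constant) for p in self.state.pneumatics
        )

    def solve_circuit(self) -> FlowSolution:
        r1, r2 = self.state.reservoirs
        t1, t2 = self.terminal_order
        return self.solver.solve({t1: r1.bottom_pressure, t2: r2.bottom_pressure})

    def step(self, dt: float) -> PlantState:
        """Advance the rig by ``dt`` seconds and return the new state."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if dt > self.min_time_constant / 5.0:
            warnings.warn(
                f"dt={dt} s is coarse relative to the fastest pneumatic time constant",
                stacklevel=2,
            )
        st = self.state
        for pneu, res in zip(st.pneumatics, st.reservoirs):
            pneu.advance(dt)
            res.applied_air_pressure = pneu.current_pressure

        sol = self.solve_circuit()
        self.last_solution = sol
        q = sol.terminal_flow(self.net, self.terminal_order[0])  # out of reservoir 1
        r1, r2 = st.reservoirs
        dv = q * dt
        donor = r1 if dv > 0 else r2
        avail = donor.liquid_volume - donor.dead_volume
        dry = False
        if abs(dv) > avail:
            dv = math.copysign(avail, dv) if avail > 0 else 0.0
            dry = True
        r1.liquid_volume -= dv
        r2.liquid_volume += dv

        self.state = PlantState(
            time=st.time + dt,
            reservoirs=st.reservoirs,
            pneumatics=st.pneumatics,
            last_flow=q,
            dry_run=dry,
        )
        return self.state

    def total_volume(self) -> float:
        return sum(r.liquid_volume for r in self.state.reservoirs)
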