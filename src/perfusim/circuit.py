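"""Steady-state hydraulic network model.

Microfluidic circuits are treated through the electrical analogy: a pressure
difference ΔP drives a volumetric flow Q through a hydraulic resistance Rh,
ΔP = Q·Rh. Channel resistances follow the laminar (Hagen–Poiseuille) formulas
for rectangular and circular cross-sections; arbitrary circuits of resistive
elements and passive check valves between pressure terminals are solved by
nodal analysis with an active-set iteration over valve open/closed states.

The quasi-static assumption holds throughout: inertial and compliant dynamics
are not modelled here (reservoir dynamics live in :mod:`perfusim.plant`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluidProperties",
    "RectangularChannel",
    "CircularTube",
    "FixedResistor",
    "CheckValve",
    "NetworkElement",
    "FluidicNetwork",
    "FlowSolution",
    "CircuitSolver",
    "InvalidGeometryError",
    "NetworkError",
    "ValveConvergenceError",
    "resistance_rectangular",
    "resistance_circular",
    "series_total",
    "parallel_total",
    "branch_flow",
    "solve_network",
    "MEDIUM_37C",
    "WATER_20C",
]


class InvalidGeometryError(ValueError):
    """A channel or tube dimension is non-positive."""


class NetworkError(ValueError):
    """The network description is structurally invalid."""


class ValveConvergenceError(RuntimeError):
    """The check-valve active-set iteration failed to reach complementarity.

    Carries the last open/closed assignment tried in ``last_assignment``.
    """

    def __init__(self, message: str, last_assignment: dict[str, bool]):
        super().__init__(message)
        self.last_assignment = last_assignment


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid properties.

    Parameters
    ----------
    dynamic_viscosity : float
        Dynamic viscosity µ in Pa·s.
    density : float
        Mass density ρ in kg/m³.
    label : str
        Free-text description of the fluid and temperature.
    """

    dynamic_viscosity: float
    density: float = 1000.0
    label: str = ""

    def __post_init__(self):
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")


#: Cell-culture medium with 2% serum at 37 °C.
MEDIUM_37C = FluidProperties(0.00079, 1005.0, "medium 2% serum 37C")
#: Deionised water at room temperature.
WATER_20C = FluidProperties(0.001, 1000.0, "water 20C")


@dataclass(frozen=True)
class RectangularChannel:
    """Rectangular duct, e.g. a moulded PDMS flow channel. Dimensions in m."""

    length: float
    width: float
    height: float

    def __post_init__(self):
        if min(self.length, self.width, self.height) <= 0:
            raise InvalidGeometryError("channel dimensions must be > 0")

    def resistance(self, fluid: FluidProperties) -> float:
        return resistance_rectangular(self, fluid)


@dataclass(frozen=True)
class CircularTube:
    """Circular tube (PTFE tubing and the like). Dimensions in m."""

    length: float
    diameter: float

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise InvalidGeometryError("tube dimensions must be > 0")

    def resistance(self, fluid: FluidProperties) -> float:
        return resistance_circular(self, fluid)


@dataclass(frozen=True)
class FixedResistor:
    """Lumped hydraulic resistance in Pa·s/m³.

    Models components whose geometry is not resolved: flow sensors,
    connectors, or a whole organ-on-chip sample treated as one resistance.
    """

    resistance_value: float

    def __post_init__(self):
        if self.resistance_value < 0:
            raise ValueError("resistance must be >= 0")

    def resistance(self, fluid: FluidProperties) -> float:
        return self.resistance_value


@dataclass(frozen=True)
class CheckValve:
    """Passive one-way valve — the fluidic analogue of a diode.

    Conducts only in its forward direction once the pressure drop exceeds
    ``cracking_pressure``; blocks reverse flow entirely. ``forward_resistance``
    is its open-state resistance; ``None`` lets the solver pick a small
    default (1e-3 of the smallest fixed resistance in the network), since
    off-the-shelf valves are far less resistive than the samples they guard.
    """

    cracking_pressure: float = 0.0
    forward_resistance: float | None = None

    def __post_init__(self):
        if self.cracking_pressure < 0:
            raise ValueError("cracking_pressure must be >= 0")
        if self.forward_resistance is not None and self.forward_resistance <= 0:
            raise ValueError("forward_resistance must be > 0")


Element = RectangularChannel | CircularTube | FixedResistor | CheckValve


@dataclass(frozen=True)
class NetworkElement:
    """A placed element: flow is positive in the from → to direction."""

    id: str
    element: Element
    node_from: str
    node_to: str


@dataclass
class FluidicNetwork:
    """Directed graph of hydraulic elements with pressure boundary conditions.

    ``terminals`` maps node ids to imposed gauge pressures in Pa. All other
    nodes are internal and their pressures are solved for.
    """

    elements: list[NetworkElement]
    terminals: dict[str, float]
    fluid: FluidProperties = WATER_20C

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for el in self.elements:
            seen.setdefault(el.node_from)
            seen.setdefault(el.node_to)
        for t in self.terminals:
            seen.setdefault(t)
        return list(seen)

    def validate(self) -> None:
        if not self.elements:
            raise NetworkError("network has no elements")
        ids = [el.id for el in self.elements]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate element ids")
        nodes = set()
        for el in self.elements:
            nodes.add(el.node_from)
            nodes.add(el.node_to)
        for t in self.terminals:
            if t not in nodes:
                raise NetworkError(f"terminal node {t!r} not attached to any element")
        if len(self.terminals) < 2:
            raise NetworkError("need at least 2 terminals for a nontrivial solve")
        for t, p in self.terminals.items():
            if not math.isfinite(p):
                raise NetworkError(f"terminal {t!r} pressure is not finite")
        # connectivity (valves counted as edges regardless of state)
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for el in self.elements:
            adj[el.node_from].add(el.node_to)
            adj[el.node_to].add(el.node_from)
        start = next(iter(self.terminals))
        stack, seen = [start], {start}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != nodes:
            raise NetworkError(f"network is disconnected: unreachable nodes {sorted(nodes - seen)}")

    def with_terminals(self, terminals: dict[str, float]) -> "FluidicNetwork":
        return FluidicNetwork(self.elements, dict(terminals), self.fluid)


@dataclass
class FlowSolution:
    """Result of a network solve.

    ``element_flows`` are signed m³/s, positive in the element's from → to
    direction. ``kcl_residual`` is the largest net-flow imbalance over the
    internal nodes, for diagnostics.
    """

    node_pressures: dict[str, float]
    element_flows: dict[str, float]
    valve_states: dict[str, bool]
    converged: bool
    kcl_residual: float = 0.0

    def terminal_flow(self, net: FluidicNetwork, terminal: str) -> float:
        """Net flow leaving ``terminal`` into the network, m³/s."""
        q = 0.0
        for el in net.elements:
            if el.node_from == terminal:
                q += self.element_flows[el.id]
            if el.node_to == terminal:
                q -= self.element_flows[el.id]
        return q


# ---------------------------------------------------------------------------
# resistance formulas and reductions


def resistance_rectangular(geom: RectangularChannel, fluid: FluidProperties) -> float:
    """Laminar resistance of a rectangular channel, Pa·s/m³.

    Rh ≈ 12µL / (w·h³·(1 − 0.63·min(w,h)/max(w,h))). The aspect-ratio
    correction uses min/max so it stays in (0, 1] whichever way the channel
    is oriented. For near-square channels this one-term approximation itself
    deviates ~10–15% from the exact infinite-series solution.
    """
    w, h = geom.width, geom.height
    corr = 1.0 - 0.63 * min(w, h) / max(w, h)
    return 12.0 * fluid.dynamic_viscosity * geom.length / (w * h**3 * corr)


def resistance_circular(geom: CircularTube, fluid: FluidProperties) -> float:
    """Hagen–Poiseuille resistance of a circular tube: 128µL/(πd⁴), Pa·s/m³."""
    return 128.0 * fluid.dynamic_viscosity * geom.length / (math.pi * geom.diameter**4)


def series_total(resistances: list[float]) -> float:
    """Total resistance of series-connected elements (sum)."""
    if any(r < 0 for r in resistances):
        raise ValueError("resistances must be >= 0")
    return float(sum(resistances))


def parallel_total(resistances: list[float]) -> float:
    """Total resistance of parallel branches: 1/R_tot = Σ 1/R_i.

    A zero entry is a short circuit and yields 0.
    """
    if not resistances:
        raise ValueError("parallel_total of no branches is undefined")
    if any(r < 0 for r in resistances):
        raise ValueError("resistances must be >= 0")
    if any(r == 0 for r in resistances):
        return 0.0
    return 1.0 / sum(1.0 / r for r in resistances)


def branch_flow(dp_ooc: float, rh_n: float) -> float:
    """Flow through one parallel sample branch: Q_n = ΔP_OoC / Rh_n.

    With a controlled pressure difference across the branch point, each
    sample's flow depends only on its own resistance — the basis of
    pressure-driven multiplexing.
    """
    if rh_n <= 0:
        raise ValueError("branch resistance must be > 0")
    return dp_ooc / rh_n


# ---------------------------------------------------------------------------
# nodal solver


class CircuitSolver:
    """Nodal solver for one network topology, reusable across solves.

    Check valves are resolved by a deterministic active-set iteration:
    start with every valve open, and per iteration flip the single valve
    whose complementarity condition is most violated (in Pa; ties broken by
    element order), until closed valves see a forward drop below cracking
    pressure and open valves carry non-negative flow. The solve for a given
    assignment is a linear system whose (pseudo-)inverse is cached, so
    repeated solves at different terminal pressures — the common case in
    time-domain simulation — cost one matrix-vector product.
    """

    #: flows smaller than this (m³/s) are not treated as reverse flow
    FLOW_TOL = 1e-18
    #: pressure slack (Pa) on the cracking condition
    PRESSURE_TOL = 1e-9

    def __init__(self, net: FluidicNetwork):
        net.validate()
        self.net = net
        self.nodes = net.nodes
        self.internal = [n for n in self.nodes if n not in net.terminals]
        self._idx = {n: i for i, n in enumerate(self.internal)}
        self.valve_ids = [el.id for el in net.elements if isinstance(el.element, CheckValve)]
        self._resist = self._element_resistances()
        self._inv_cache: dict[frozenset, tuple] = {}

    def _element_resistances(self) -> dict[str, float]:
        res: dict[str, float] = {}
        fixed = []
        for el in self.net.elements:
            if not isinstance(el.element, CheckValve):
                r = el.element.resistance(self.net.fluid)
                res[el.id] = r
                if r > 0:
                    fixed.append(r)
        default_valve_r = 1e-3 * min(fixed) if fixed else 1e6
        for el in self.net.elements:
            if isinstance(el.element, CheckValve):
                r = el.element.forward_resistance
                res[el.id] = default_valve_r if r is None else r
        return res

    def _assemble(self, open_valves: frozenset):
        """Conductance matrix, terminal-coupling terms, and constant RHS.

        The RHS splits into a constant part (valve cracking-pressure EMFs)
        and terms linear in the terminal pressures, so a cached assignment
        can be re-solved at new terminal pressures without reassembly.
        """
        n = len(self.internal)
        G = np.zeros((n, n))
        b_const = np.zeros(n)
        term_coupling: list[tuple[int, float, str]] = []  # (row, conductance, terminal)
        for el in self.net.elements:
            is_valve = isinstance(el.element, CheckValve)
            if is_valve and el.id not in open_valves:
                continue
            r = self._resist[el.id]
            g = 1.0 / r if r > 0 else 1e18  # zero-resistance element: near-ideal short
            pc = el.element.cracking_pressure if is_valve else 0.0
            fa, ta = el.node_from, el.node_to
            for node, sign in ((fa, 1.0), (ta, -1.0)):
                if node not in self._idx:
                    continue
                i = self._idx[node]
                G[i, i] += g
                other = ta if node == fa else fa
                if other in self._idx:
                    G[i, self._idx[other]] -= g
                else:
                    term_coupling.append((i, g, other))
                # an open valve's cracking pressure acts like a series EMF
                b_const[i] += sign * g * pc
        return G, b_const, term_coupling

    def _solve_assignment(self, open_valves: frozenset) -> dict[str, float]:
        n = len(self.internal)
        if n == 0:
            return {}
        if open_valves not in self._inv_cache:
            G, b_const, coupling = self._assemble(open_valves)
            try:
                inv = np.linalg.inv(G)
            except np.linalg.LinAlgError:
                # closed valves may isolate nodes; pinv pins floating nodes
                inv = np.linalg.pinv(G)
            self._inv_cache[open_valves] = (inv, b_const, coupling)
        inv, b_const, coupling = self._inv_cache[open_valves]
        b = b_const.copy()
        for i, g, terminal in coupling:
            b[i] += g * self.net.terminals[terminal]
        p = inv @ b
        return dict(zip(self.internal, p))

    def _flows(self, pressures: dict[str, float], open_valves: frozenset) -> dict[str, float]:
        full = {**pressures, **self.net.terminals}
        flows: dict[str, float] = {}
        for el in self.net.elements:
            dp = full[el.node_from] - full[el.node_to]
            if isinstance(el.element, CheckValve):
                if el.id not in open_valves:
                    flows[el.id] = 0.0
                    continue
                dp -= el.element.cracking_pressure
            r = self._resist[el.id]
            flows[el.id] = dp / r if r > 0 else dp * 1e18
        return flows

    def solve(self, terminals: dict[str, float] | None = None) -> FlowSolution:
        """Solve node pressures and element flows.

        ``terminals`` overrides the network's terminal pressures for this
        solve (the topology and element set are unchanged).
        """
        if terminals is not None:
            if set(terminals) != set(self.net.terminals):
                raise NetworkError("terminal override must name the same nodes")
            self.net.terminals = dict(terminals)
        open_valves = frozenset(self.valve_ids)
        max_iter = max(2 ** len(self.valve_ids), 1)
        tried = []
        for _ in range(max_iter):
            pressures = self._solve_assignment(open_valves)
            flows = self._flows(pressures, open_valves)
            worst_id, worst_violation = None, 0.0
            full = {**pressures, **self.net.terminals}
            for el in self.net.elements:
                if not isinstance(el.element, CheckValve):
                    continue
                dp = full[el.node_from] - full[el.node_to]
                pc = el.element.cracking_pressure
                if el.id in open_valves:
                    if flows[el.id] < -self.FLOW_TOL:
                        v = pc - dp  # how far below cracking the drop has fallen
                        if v > worst_violation:
                            worst_id, worst_violation = el.id, v
                else:
                    if dp > pc + self.PRESSURE_TOL:
                        v = dp - pc
                        if v > worst_violation:
                            worst_id, worst_violation = el.id, v
            if worst_id is None:
                return self._finalize(pressures, flows, open_valves)
            tried.append(open_valves)
            open_valves = (
                open_valves - {worst_id} if worst_id in open_valves else open_valves | {worst_id}
            )
        raise ValveConvergenceError(
            f"valve active-set iteration did not converge in {max_iter} iterations",
            {vid: (vid in open_valves) for vid in self.valve_ids},
        )

    def _finalize(self, pressures, flows, open_valves) -> FlowSolution:
        net_flow = {n: 0.0 for n in self.internal}
        for el in self.net.elements:
            q = flows[el.id]
            if el.node_from in net_flow:
                net_flow[el.node_from] -= q
            if el.node_to in net_flow:
                net_flow[el.node_to] += q
        residual = max((abs(v) for v in net_flow.values()), default=0.0)
        return FlowSolution(
            node_pressures={**pressures, **self.net.terminals},
            element_flows=flows,
            valve_states={vid: (vid in open_valves) for vid in self.valve_ids},
            converged=True,
            kcl_residual=residual,
        )


def solve_network(net: FluidicNetwork) -> FlowSolution:
    """One-shot solve of a network (see :class:`CircuitSolver`)."""
    return CircuitSolver(net).solve()
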