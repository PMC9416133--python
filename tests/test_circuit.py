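"""Hydraulic resistance formulas and the nodal network solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfusim.circuit import (
    CheckValve,
    CircuitSolver,
    CircularTube,
    FixedResistor,
    FluidProperties,
    FluidicNetwork,
    InvalidGeometryError,
    MEDIUM_37C,
    NetworkElement,
    NetworkError,
    RectangularChannel,
    WATER_20C,
    branch_flow,
    parallel_total,
    resistance_circular,
    resistance_rectangular,
    series_total,
    solve_network,
)
from perfusim.units import m3s_to_ulmin

from conftest import random_ladder


class TestResistanceFormulas:
    def test_rectangular_chip_channel(self):
        # 1.1 cm × 500 µm × 500 µm channel in 0.00079 Pa·s medium
        rh = resistance_rectangular(RectangularChannel(0.011, 500e-6, 500e-6), MEDIUM_37C)
        assert rh == pytest.approx(4.51e9, rel=1e-3)

    def test_circular_loop_tube(self):
        rh = resistance_circular(CircularTube(0.08, 250e-6), WATER_20C)
        assert rh == pytest.approx(8.344e11, rel=1e-3)

    def test_rectangular_linear_in_length(self):
        fluid = WATER_20C
        r1 = resistance_rectangular(RectangularChannel(0.01, 4e-4, 2e-4), fluid)
        r2 = resistance_rectangular(RectangularChannel(0.02, 4e-4, 2e-4), fluid)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_square_channel_correction_is_037(self):
        # w = h makes the aspect-ratio correction exactly 1 − 0.63
        geom = RectangularChannel(0.01, 3e-4, 3e-4)
        rh = resistance_rectangular(geom, WATER_20C)
        expected = 12 * WATER_20C.dynamic_viscosity * 0.01 / (3e-4 * (3e-4) ** 3 * 0.37)
        assert rh == pytest.approx(expected, rel=1e-12)

    def test_aspect_ratio_orientation_invariant(self):
        fluid = WATER_20C
        wide = resistance_rectangular(RectangularChannel(0.01, 6e-4, 2e-4), fluid)
        tall_corr = 1 - 0.63 * (2e-4 / 6e-4)
        assert 0 < tall_corr <= 1
        assert wide == pytest.approx(
            12 * fluid.dynamic_viscosity * 0.01 / (6e-4 * (2e-4) ** 3 * tall_corr), rel=1e-12
        )

    def test_tube_fourth_power_law(self):
        fluid = WATER_20C
        r1 = resistance_circular(CircularTube(0.1, 4e-4), fluid)
        r2 = resistance_circular(CircularTube(0.1, 2e-4), fluid)
        assert r2 == pytest.approx(16 * r1, rel=1e-12)

    @pytest.mark.parametrize(
        "geom",
        [
            lambda: RectangularChannel(0.0, 1e-4, 1e-4),
            lambda: RectangularChannel(0.01, -1e-4, 1e-4),
            lambda: CircularTube(0.0, 1e-4),
            lambda: CircularTube(0.01, 0.0),
        ],
    )
    def test_nonpositive_dimension_rejected(self, geom):
        with pytest.raises(InvalidGeometryError):
            geom()

    def test_positivity(self, rng):
        for _ in range(20):
            dims = rng.uniform(1e-5, 1e-2, size=3)
            assert resistance_rectangular(RectangularChannel(*dims), WATER_20C) > 0
            assert resistance_circular(CircularTube(dims[0], dims[1]), WATER_20C) > 0


class TestReductions:
    def test_series(self):
        assert series_total([1e9, 2e9, 3e9]) == pytest.approx(6e9)
        assert series_total([5e8, 0.0]) == 5e8
        assert series_total([]) == 0.0
        vals = [3e9, 1e9, 7e9]
        assert series_total(vals) == series_total(vals[::-1])

    def test_parallel(self):
        assert parallel_total([2e9, 2e9]) == pytest.approx(1e9)
        assert parallel_total([6e9] * 6) == pytest.approx(1e9)
        assert parallel_total([4e9]) == pytest.approx(4e9, rel=1e-12)
        assert parallel_total([1e9, 0.0]) == 0.0
        with pytest.raises(ValueError):
            parallel_total([])

    def test_branch_flow(self):
        assert branch_flow(0.0, 1e9) == 0.0
        # ~29 mbar across the long-term loop gives roughly 200 µL/min
        q = branch_flow(2900.0, 8.344e11)
        assert m3s_to_ulmin(q) == pytest.approx(208.5, rel=5e-3)
        assert branch_flow(200.0, 1e9) == pytest.approx(2 * branch_flow(100.0, 1e9))
        with pytest.raises(ValueError):
            branch_flow(100.0, 0.0)


class TestSolver:
    def test_two_series_resistors(self):
        net = FluidicNetwork(
            [
                NetworkElement("a", FixedResistor(1e9), "in", "mid"),
                NetworkElement("b", FixedResistor(3e9), "mid", "out"),
            ],
            {"in": 1000.0, "out": 0.0},
        )
        sol = solve_network(net)
        q_expected = 1000.0 / series_total([1e9, 3e9])
        assert sol.element_flows["a"] == pytest.approx(q_expected, rel=1e-9)
        assert sol.element_flows["b"] == pytest.approx(q_expected, rel=1e-9)
        assert sol.node_pressures["mid"] == pytest.approx(750.0, rel=1e-9)

    def test_random_ladders_match_reduction(self, rng):
        for _ in range(20):
            net, reduced = random_ladder(rng)
            net.terminals = {"inlet": 2900.0, "outlet": 0.0}
            sol = solve_network(net)
            q = sol.terminal_flow(net, "inlet")
            assert q == pytest.approx(2900.0 / reduced, rel=1e-9)
            assert sol.kcl_residual <= 1e-12 * max(abs(f) for f in sol.element_flows.values())

    def test_parallel_ladder_matches_branch_flow(self, rng):
        """With negligible shared resistance each branch obeys Q = dP/Rh."""
        elements, rhs = [], []
        for b in range(6):
            r = float(rng.uniform(1e9, 1e12))
            rhs.append(r)
            elements.append(NetworkElement(f"b{b}", FixedResistor(r), "in", "out"))
        net = FluidicNetwork(elements, {"in": 2900.0, "out": 0.0})
        sol = solve_network(net)
        for b, r in enumerate(rhs):
            assert sol.element_flows[f"b{b}"] == pytest.approx(branch_flow(2900.0, r), rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(k=st.floats(min_value=-50.0, max_value=50.0, allow_nan=False))
    def test_linearity_in_terminal_pressures(self, k):
        rng = np.random.default_rng(7)
        net, _ = random_ladder(rng, n_branches=3)
        base = solve_network(net.with_terminals({"inlet": 800.0, "outlet": 100.0}))
        scaled = solve_network(net.with_terminals({"inlet": 100.0 + k * 700.0, "outlet": 100.0}))
        for eid, q in base.element_flows.items():
            assert scaled.element_flows[eid] == pytest.approx(k * q, rel=1e-9, abs=1e-22)

    def test_disconnected_raises(self):
        net = FluidicNetwork(
            [
                NetworkElement("a", FixedResistor(1e9), "in", "out"),
                NetworkElement("b", FixedResistor(1e9), "x", "y"),
            ],
            {"in": 100.0, "out": 0.0},
        )
        with pytest.raises(NetworkError, match="disconnected"):
            solve_network(net)

    def test_single_terminal_rejected(self):
        net = FluidicNetwork(
            [NetworkElement("a", FixedResistor(1e9), "in", "out")], {"in": 100.0}
        )
        with pytest.raises(NetworkError):
            solve_network(net)


def graetz_net(cracking=0.0):
    sample = FixedResistor(1e10)
    return FluidicNetwork(
        [
            NetworkElement("v1", CheckValve(cracking), "res1", "s_in"),
            NetworkElement("v2", CheckValve(cracking), "s_out", "res2"),
            NetworkElement("v3", CheckValve(cracking), "res2", "s_in"),
            NetworkElement("v4", CheckValve(cracking), "s_out", "res1"),
            NetworkElement("sample", sample, "s_in", "s_out"),
        ],
        {"res1": 0.0, "res2": 0.0},
    )


class TestCheckValves:
    def test_bridge_rectifies(self):
        net = graetz_net()
        solver = CircuitSolver(net)
        fwd = solver.solve({"res1": 3000.0, "res2": 100.0})
        rev = solver.solve({"res1": 100.0, "res2": 3000.0})
        assert fwd.element_flows["sample"] > 0
        assert rev.element_flows["sample"] > 0
        assert math.copysign(1, fwd.terminal_flow(net, "res1")) == -math.copysign(
            1, rev.terminal_flow(net, "res1")
        )
        assert fwd.valve_states == {"v1": True, "v2": True, "v3": False, "v4": False}
        assert rev.valve_states == {"v1": False, "v2": False, "v3": True, "v4": True}
        for sol in (fwd, rev):
            for vid, is_open in sol.valve_states.items():
                if not is_open:
                    assert sol.element_flows[vid] == 0.0
                else:
                    assert sol.element_flows[vid] >= 0.0

    def test_bridge_zero_at_equal_pressures(self):
        sol = CircuitSolver(graetz_net()).solve({"res1": 500.0, "res2": 500.0})
        assert all(abs(q) < 1e-18 for q in sol.element_flows.values())

    def test_cracking_pressure_blocks_small_dp(self):
        net = FluidicNetwork(
            [
                NetworkElement("v", CheckValve(cracking_pressure=200.0), "in", "mid"),
                NetworkElement("r", FixedResistor(1e9), "mid", "out"),
            ],
            {"in": 150.0, "out": 0.0},
        )
        sol = solve_network(net)
        assert sol.element_flows["v"] == 0.0
        assert not sol.valve_states["v"]

    def test_cracking_pressure_subtracts_when_open(self):
        rv, rr = 1e8, 1e9
        net = FluidicNetwork(
            [
                NetworkElement("v", CheckValve(200.0, rv), "in", "mid"),
                NetworkElement("r", FixedResistor(rr), "mid", "out"),
            ],
            {"in": 1000.0, "out": 0.0},
        )
        sol = solve_network(net)
        assert sol.element_flows["r"] == pytest.approx((1000.0 - 200.0) / (rv + rr), rel=1e-9)

    def test_opposing_valves_resolve_deterministically(self):
        # the reverse-oriented valve must close; the active set settles
        net = FluidicNetwork(
            [
                NetworkElement("v1", CheckValve(), "in", "mid"),
                NetworkElement("v2", CheckValve(), "out", "mid"),
                NetworkElement("r", FixedResistor(1e9), "mid", "out"),
            ],
            {"in": 1000.0, "out": 0.0},
        )
        sol = solve_network(net)  # this one converges (v2 closes)
        assert sol.converged
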