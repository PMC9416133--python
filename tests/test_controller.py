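"""PID pressure-difference control, switching logic and closed-loop runs."""

import math

import numpy as np
import pandas as pd
import pytest

from perfusim.controller import (
    ControllerConfig,
    PIDGains,
    PIDState,
    execute_switch,
    pid_update,
    run_experiment,
    should_switch,
)
from perfusim.fixtures import graetz_bridge_network, make_plant, tubing_loop_network
from perfusim.sensors import GaugePressurePair


def quiet_gauge(**kw):
    return GaugePressurePair(noise_sd=0.0, **kw)


class TestPIDUpdate:
    def test_at_setpoint_commands_stationary(self):
        state = PIDState()
        cfg = ControllerConfig()
        c1 = pid_update(state, cfg, 29.0, 50.0, 0.1)
        c2 = pid_update(state, cfg, 29.0, 50.0, 0.1)
        assert c1 == c2

    def test_command_decomposition(self):
        state = PIDState(integral=29.0 / 0.2)  # integral already carrying the setpoint
        cfg = ControllerConfig()
        cmd1, cmd2 = pid_update(state, cfg, 29.0, 50.0, 0.1)
        assert cmd1 - cmd2 == pytest.approx(29.0)
        assert 0.5 * (cmd1 + cmd2) == pytest.approx(50.0)

    def test_p_ooc_raises_both_commands_equally(self):
        s1, s2 = PIDState(), PIDState()
        lo = pid_update(s1, ControllerConfig(p_ooc_setpoint=50.0), 20.0, 50.0, 0.1)
        hi = pid_update(s2, ControllerConfig(p_ooc_setpoint=80.0), 20.0, 80.0, 0.1)
        assert hi[0] - lo[0] == pytest.approx(30.0)
        assert hi[1] - lo[1] == pytest.approx(30.0)

    def test_anti_windup_freezes_integral(self):
        state = PIDState()
        cfg = ControllerConfig(p_ooc_setpoint=340.0, dp_setpoint=100.0)
        pid_update(state, cfg, 0.0, 0.0, 0.1)  # demands cmd1 > 345 → clamp
        assert state.anti_windup_active
        assert state.integral == 0.0

    def test_nan_measurement_holds_last_command(self):
        state = PIDState()
        cfg = ControllerConfig()
        last = pid_update(state, cfg, 25.0, 50.0, 0.1)
        held = pid_update(state, cfg, float("nan"), 50.0, 0.1)
        assert held == last
        assert state.anti_windup_active

    def test_negative_gains_rejected(self):
        with pytest.raises(ValueError):
            PIDGains(kp=-0.1)


class TestSwitchLogic:
    def test_donor_below_threshold_triggers(self):
        cfg = ControllerConfig(switch_low_volume=2.0, hysteresis=0.25)
        assert should_switch((1.75, 8.0), cfg, current_direction=1)
        assert not should_switch((2.05, 8.0), cfg, current_direction=1)
        # reversed direction: reservoir 2 is the donor
        assert should_switch((8.0, 1.75), cfg, current_direction=-1)

    def test_lockout_suppresses(self):
        cfg = ControllerConfig(switch_lockout_s=30.0)
        assert not should_switch((1.0, 8.0), cfg, 1, time_since_switch=5.0)
        assert should_switch((1.0, 8.0), cfg, 1, time_since_switch=31.0)

    def test_stale_readings_conservative(self):
        cfg = ControllerConfig()
        with pytest.warns(UserWarning, match="stale"):
            assert not should_switch((0.5, 8.0), cfg, 1, readings_fresh=False)

    def test_no_chatter_with_noisy_level(self):
        cfg = ControllerConfig(switch_low_volume=2.0, hysteresis=0.25, switch_lockout_s=30.0)
        rng = np.random.default_rng(3)
        direction, t_since, switches = 1, math.inf, []
        for k in range(600):  # 60 s of 10 Hz level readings hovering at threshold
            level = 1.75 + rng.normal(0.0, 0.05)
            if should_switch((level, 8.0), cfg, direction, t_since):
                switches.append(k * 0.1)
                direction, t_since = -direction, 0.0
            else:
                t_since += 0.1
        if len(switches) > 1:
            assert min(np.diff(switches)) >= cfg.switch_lockout_s

    def test_execute_switch_involution(self):
        cmds, direction = (40.0, 20.0), 1
        c1, d1, v1 = execute_switch("graetz", cmds, direction)
        c2, d2, _ = execute_switch("graetz", c1, d1)
        assert (c2, d2) == (cmds, direction)

    def test_active_valve_toggles_both(self):
        _, _, valves = execute_switch("active_valve", (40.0, 20.0), 1, (False, False))
        assert valves == (True, True)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            execute_switch("bogus", (1.0, 0.0), 1)


class TestRunExperiment:
    def test_zero_duration_empty_telemetry(self):
        plant = make_plant(tubing_loop_network())
        result = run_experiment(plant, ControllerConfig(), 0.0, seed=1)
        assert len(result.telemetry) == 0
        assert result.aborted is None

    def test_same_seed_identical_telemetry(self):
        cfg = ControllerConfig(sample_element_id="sample")
        runs = []
        for _ in range(2):
            plant = make_plant(tubing_loop_network())
            runs.append(run_experiment(plant, cfg, 20.0, seed=11).telemetry)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_setpoint_tracked_after_settling(self):
        plant = make_plant(tubing_loop_network())
        cfg = ControllerConfig(sample_element_id="sample")
        tel = run_experiment(plant, cfg, 120.0, seed=5).telemetry
        post = tel[tel.time_s > 60.0]
        assert (abs(post.dp_mbar - 29.0) < 0.02 * 29.0).mean() > 0.95

    def test_back_pressure_decoupling(self):
        """Steady flow shifts < 0.5% when the P_OoC target changes."""
        flows = []
        for p_ooc in (50.0, 90.0):
            plant = make_plant(tubing_loop_network())
            cfg = ControllerConfig(p_ooc_setpoint=p_ooc, sample_element_id="sample")
            tel = run_experiment(
                plant, cfg, 120.0, seed=7, gauge_pair=quiet_gauge()
            ).telemetry
            flows.append(tel[tel.time_s > 60.0].q_true_ulmin.mean())
        assert abs(flows[1] - flows[0]) / flows[0] < 0.005

    def test_graetz_switch_keeps_sample_unidirectional(self):
        plant = make_plant(graetz_bridge_network(), initial_volumes_ml=(2.6, 3.0))
        cfg = ControllerConfig(
            mode="graetz",
            sample_element_id="sample",
            switch_low_volume=2.0,
            switch_high_volume=5.0,
            switch_lockout_s=20.0,
        )
        result = run_experiment(plant, cfg, 300.0, seed=9)
        tel = result.telemetry
        assert (tel.direction == -1).any(), "expected at least one switch"
        assert (tel.q_true_ulmin >= -1e-9).all()
        # reservoir-side dP reverses sign across the switch
        assert (tel.dp_mbar * tel.direction > 0)[tel.time_s > 60.0].mean() > 0.95

    def test_active_valve_desync_causes_backflow(self):
        def run(lag):
            plant = make_plant(tubing_loop_network(), initial_volumes_ml=(2.2, 2.0))
            cfg = ControllerConfig(
                mode="active_valve",
                sample_element_id="sample",
                switch_low_volume=2.0,
                switch_high_volume=5.0,
                switch_lockout_s=20.0,
            )
            return run_experiment(plant, cfg, 200.0, seed=13, valve_lag_ticks=lag).telemetry

        synced = run(0)
        lagged = run(3)
        assert (synced.direction == -1).any()
        assert (lagged.q_true_ulmin < -1.0).any(), "desync should show transient backflow"

    def test_dry_run_aborts_with_diagnostic(self):
        plant = make_plant(tubing_loop_network(), initial_volumes_ml=(1.2, 3.0))
        cfg = ControllerConfig(mode="single_pass", sample_element_id="sample")
        result = run_experiment(plant, cfg, 600.0, seed=15)
        assert result.aborted is not None and "dry" in result.aborted

    def test_notification_hook_per_sequence(self):
        seen = []
        plant = make_plant(graetz_bridge_network(), initial_volumes_ml=(2.2, 2.0))
        cfg = ControllerConfig(
            mode="graetz",
            sample_element_id="sample",
            switch_low_volume=2.0,
            switch_high_volume=5.0,
            switch_lockout_s=20.0,
        )
        result = run_experiment(plant, cfg, 200.0, seed=17, notification_hook=seen.append)
        assert len(seen) == len(result.summaries) >= 2
        total_displaced = sum(s.displaced_volume_ml for s in result.summaries)
        assert total_displaced == pytest.approx(
            (result.telemetry.q_true_ulmin.abs().mean() / 60.0) * result.telemetry.time_s.iloc[-1] / 1000.0,
            rel=0.1,
        )
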