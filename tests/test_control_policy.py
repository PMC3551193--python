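"""Titration state machine, CS/DNE program, interlocks, trace validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neuroloop.control_policy import (ControllerConfig, EmbeddedController,
                                      HybridController, HybridProgram, Loop,
                                      Observation, Phase, validate_trace)

DT = 0.2


def run_cycle(ctrl, obs_on=None, obs_off=None):
    """Drive one full on+off cycle; returns amplitude at the next ON start."""
    c = ctrl.cfg
    while ctrl.phase is Phase.ON:
        ctrl.step(obs_on or Observation(), DT)
    while ctrl.phase in (Phase.OFF, Phase.ABORTED):
        ctrl.step(obs_off or Observation(), DT)
    return ctrl.amplitude


class TestEmbeddedController:
    def test_ad_abort_immediate_and_decrement(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.7))
        stim = ctrl.step(Observation(ad_detected=True), DT)
        assert not stim.on  # stim off on the same control step
        assert ctrl.amplitude_mv == 1600
        assert ctrl.ceiling_mv == 1600
        assert ctrl.loop is Loop.AFTER_DISCHARGE

    def test_suppression_holds_amplitude(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.6))
        amp = run_cycle(ctrl, obs_off=Observation(suppression_detected=True))
        assert amp == pytest.approx(1.6)
        assert ctrl.loop is Loop.SUPPRESSION

    def test_two_resting_cycles_increment_to_ceiling_probe(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.6))
        assert run_cycle(ctrl) == pytest.approx(1.65)
        assert run_cycle(ctrl) == pytest.approx(1.70)
        assert ctrl.loop is Loop.RESTING

    def test_single_resting_step_is_exactly_50mv(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.0))
        before = ctrl.amplitude_mv
        run_cycle(ctrl)
        assert ctrl.amplitude_mv - before == 50

    def test_single_ad_step_is_exactly_minus_100mv(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.0))
        before = ctrl.amplitude_mv
        ctrl.step(Observation(ad_detected=True), DT)
        assert ctrl.amplitude_mv - before == -100

    def test_mid_phase_observations_do_not_change_amplitude(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.2))
        for _ in range(10):  # mid-ON, no detections: timers only
            ctrl.step(Observation(), DT)
        assert ctrl.amplitude_mv == 1200
        assert ctrl.phase is Phase.ON

    def test_resting_increment_clamped_at_amp_max(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.7))
        run_cycle(ctrl)
        assert ctrl.amplitude_mv == 1700

    def test_ad_decrement_clamped_at_amp_min(self):
        cfg = ControllerConfig(initial_amplitude=0.05, amp_min=0.0)
        ctrl = EmbeddedController(cfg)
        ctrl.step(Observation(ad_detected=True), DT)
        assert ctrl.amplitude_mv == 0

    def test_persistent_ad_flag_decrements_once(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.7))
        for _ in range(10):
            ctrl.step(Observation(ad_detected=True), DT)
        assert ctrl.amplitude_mv == 1600  # edge-triggered, not level

    def test_slow_attack_fast_recovery(self):
        # equal counts of resting and AD events: net change negative
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.0))
        start = ctrl.amplitude_mv
        for _ in range(3):
            run_cycle(ctrl)  # resting increment
            ctrl.step(Observation(ad_detected=True), DT)  # AD decrement
            while ctrl.phase is not Phase.ON:
                ctrl.step(Observation(), DT)
        assert ctrl.amplitude_mv < start

    def test_transition_log_time_ordered(self):
        ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.6))
        run_cycle(ctrl)
        ctrl.step(Observation(ad_detected=True), DT)
        run_cycle(ctrl)
        ts = [tr.t for tr in ctrl.transition_log]
        assert ts == sorted(ts)

    def test_determinism_identical_observation_sequences(self):
        def run():
            ctrl = EmbeddedController(ControllerConfig(initial_amplitude=1.5))
            rng = np.random.default_rng(9)
            for _ in range(2000):
                ctrl.step(Observation(ad_detected=rng.random() < 0.01,
                                      suppression_detected=rng.random() < 0.2),
                          DT)
            return [(tr.t, tr.to_loop, tr.amplitude_mv)
                    for tr in ctrl.transition_log]
        assert run() == run()

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=300),
           st.floats(0.05, 2.0))
    def test_interlock_never_violated(self, flags, dt):
        cfg = ControllerConfig(initial_amplitude=1.0, amp_min=0.0,
                               amp_max=1.7)
        ctrl = EmbeddedController(cfg)
        for ad, sup in flags:
            stim = ctrl.step(Observation(ad, sup), dt)
            assert 0.0 <= stim.amplitude <= 1.7
            assert cfg.amp_min_mv <= ctrl.amplitude_mv <= cfg.amp_max_mv

    def test_interlock_fuzz_large(self):
        # 1e5 random detection steps, amplitude always inside the interlock
        rng = np.random.default_rng(77)
        cfg = ControllerConfig(initial_amplitude=1.2)
        ctrl = EmbeddedController(cfg)
        for _ in range(100_000):
            stim = ctrl.step(
                Observation(ad_detected=bool(rng.random() < 0.005),
                            suppression_detected=bool(rng.random() < 0.3)),
                float(rng.uniform(0.05, 1.0)))
            assert cfg.amp_min_mv <= ctrl.amplitude_mv <= cfg.amp_max_mv
            assert 0.0 <= stim.amplitude <= cfg.amp_max

    def test_strict_ceiling_mode_blocks_reprobe(self):
        cfg = ControllerConfig(initial_amplitude=1.7, strict_ceiling=True)
        ctrl = EmbeddedController(cfg)
        ctrl.step(Observation(ad_detected=True), DT)  # ceiling 1.6
        while ctrl.phase is not Phase.ON:
            ctrl.step(Observation(), DT)
        run_cycle(ctrl)  # resting: would increment to 1.65, ceiling says no
        assert ctrl.amplitude_mv == 1600

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(increment=0.2, decrement=0.1)
        with pytest.raises(ValueError):
            ControllerConfig(initial_amplitude=2.0)


class TestHybridController:
    def test_no_ad_cycles_identical_cs_deliveries(self):
        hc = HybridController()
        amps = []
        for _ in range(round(200 / DT)):
            stim = hc.step(False, DT)
            if stim.on:
                amps.append(stim.amplitude)
        assert set(amps) == {1.50}

    def test_ad_halts_within_one_step_then_dne(self):
        hc = HybridController()
        hc.step(False, DT)
        stim = hc.step(True, DT)
        assert not stim.on  # halted on the detection step
        t = 0.0
        while not hc.step(False, DT).on:
            t += DT
            assert t < 60
        assert hc.amplitude == pytest.approx(1.25)

    def test_returns_to_cs_after_one_dne_cycle(self):
        hc = HybridController(HybridProgram(dne_delay=1.0))
        hc.step(True, DT)
        seen = []
        for _ in range(round(150 / DT)):
            stim = hc.step(False, DT)
            if stim.on:
                seen.append(stim.amplitude)
        assert 1.25 in seen and seen[-1] == 1.50
        # one DNE on-phase of 25 s at 5 Hz stepping
        assert seen.count(1.25) == pytest.approx(125, abs=2)

    def test_ad_during_dne_reschedules(self):
        hc = HybridController(HybridProgram(dne_delay=1.0))
        hc.step(True, DT)
        while not hc.step(False, DT).on:
            pass
        assert hc.amplitude == pytest.approx(1.25)
        stim = hc.step(True, DT)  # AD during the DNE cycle
        assert not stim.on
        while not hc.step(False, DT).on:
            pass
        assert hc.amplitude == pytest.approx(1.25)  # DNE delivered again

    def test_detection_disabled_never_halts(self):
        hc = HybridController(detection_enabled=False)
        stim = hc.step(True, DT)
        assert stim.on and stim.amplitude == 1.50


class TestValidateTrace:
    def test_empty_vs_empty_passes(self):
        assert validate_trace([], []).passed

    def test_exact_match_passes(self):
        r = validate_trace([1700, 1600, 1600], [1700, 1600, 1600])
        assert r.passed and r.diverged_at is None

    def test_first_divergence_reported(self):
        r = validate_trace([1700, 1650], [1700, 1600])
        assert not r.passed and r.diverged_at == 1

    def test_length_mismatch_fails_at_missing_index(self):
        r = validate_trace([1700], [1700, 1600])
        assert not r.passed and r.diverged_at == 1
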