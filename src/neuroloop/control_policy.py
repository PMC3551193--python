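"""Embedded stimulation-titration state machines.

Two controllers are provided:

* :class:`EmbeddedController` — the merged three-loop titration policy.  A
  shared stimulation sequence cycles stimulation on and off; classified
  observations steer amplitude:

  - *after-discharge loop*: an AD detection aborts stimulation on the same
    control step, decrements amplitude by 0.10 V and records the new value
    as the current safe ceiling;
  - *suppression loop*: suppression observed during the post-stimulation off
    phase holds the amplitude for the next cycle;
  - *resting loop*: with neither observed, amplitude increments by 0.05 V
    (slow attack, fast recovery) to re-probe the ceiling.

  Amplitude arithmetic is done in integer millivolts so repeated ±50/100 mV
  steps can never drift, and every commanded value is clamped inside the
  pre-programmed [amp_min, amp_max] interlock.

* :class:`HybridController` — the externally-prototyped auto-shutoff
  program: cycle stimulation (CS) at 1.50 V until an AD is detected, then
  halt immediately and, after a programmed delay, deliver one cycle of the
  decreased-network-excitability (DNE) program at 1.25 V before resuming CS.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .plant import StimInput

__all__ = [
    "Loop",
    "Phase",
    "Observation",
    "ControllerConfig",
    "HybridProgram",
    "EmbeddedController",
    "HybridController",
    "TraceReport",
    "validate_trace",
]

_EPS = 1e-9


class Loop(str, Enum):
    SUPPRESSION = "SUPPRESSION"
    AFTER_DISCHARGE = "AFTER_DISCHARGE"
    RESTING = "RESTING"
    STIM_SEQUENCE = "STIM_SEQUENCE"


class Phase(str, Enum):
    ON = "ON"
    OFF = "OFF"
    ABORTED = "ABORTED"


@dataclass(frozen=True)
class Observation:
    ad_detected: bool = False
    suppression_detected: bool = False


@dataclass
class ControllerConfig:
    increment: float = 0.05  # volts per resting-loop step
    decrement: float = 0.10  # volts per AD abort (slow attack, fast recovery)
    amp_min: float = 0.0
    amp_max: float = 1.7  # programmable interlock
    initial_amplitude: float = 1.7
    cycle_on: float = 25.0  # seconds
    cycle_off: float = 25.0
    stim_frequency: float = 120.0
    pulse_width: float = 300.0
    strict_ceiling: bool = False  # if True, resting loop never exceeds ceiling

    def __post_init__(self) -> None:
        if not (0 < self.increment < self.decrement):
            raise ValueError("require 0 < increment < decrement")
        if not (self.amp_min <= self.initial_amplitude <= self.amp_max):
            raise ValueError("initial amplitude outside [amp_min, amp_max]")
        if self.cycle_on <= 0 or self.cycle_off <= 0:
            raise ValueError("cycle durations must be positive")

    @property
    def increment_mv(self) -> int:
        return round(self.increment * 1000)

    @property
    def decrement_mv(self) -> int:
        return round(self.decrement * 1000)

    @property
    def amp_min_mv(self) -> int:
        return round(self.amp_min * 1000)

    @property
    def amp_max_mv(self) -> int:
        return round(self.amp_max * 1000)


@dataclass
class HybridProgram:
    cs_amplitude: float = 1.50  # volts, AD-capable cycle stimulation
    dne_amplitude: float = 1.25  # volts, decreased-network-excitability
    dne_delay: float = 5.0  # seconds between abort and the DNE delivery
    dne_cycles: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.dne_amplitude < self.cs_amplitude):
            raise ValueError("require dne_amplitude < cs_amplitude")
        if self.dne_delay < 0 or self.dne_cycles < 1:
            raise ValueError("dne_delay >= 0 and dne_cycles >= 1 required")


@dataclass
class Transition:
    t: float
    from_loop: Loop
    to_loop: Loop
    amplitude_mv: int
    phase: Phase

    def as_dict(self) -> dict:
        return {"t": self.t, "from_loop": self.from_loop.value,
                "to_loop": self.to_loop.value,
                "amplitude_mV": self.amplitude_mv, "phase": self.phase.value}


class EmbeddedController:
    """Three-loop titration state machine over a shared stimulation sequence."""

    def __init__(self, cfg: ControllerConfig | None = None) -> None:
        self.cfg = cfg if cfg is not None else ControllerConfig()
        c = self.cfg
        self.loop = Loop.STIM_SEQUENCE
        self.amplitude_mv = round(c.initial_amplitude * 1000)
        self.ceiling_mv = c.amp_max_mv
        self.phase = Phase.ON
        self.phase_elapsed = 0.0
        self.t = 0.0
        self.transition_log: list[Transition] = []
        self._suppression_seen = False
        self._prev_ad = False
        self._adjusted_this_cycle = False
        self._log(Loop.STIM_SEQUENCE)

    # ------------------------------------------------------------------
    @property
    def amplitude(self) -> float:
        return self.amplitude_mv / 1000.0

    def _log(self, to_loop: Loop) -> None:
        self.transition_log.append(Transition(
            t=self.t, from_loop=self.loop, to_loop=to_loop,
            amplitude_mv=self.amplitude_mv, phase=self.phase))
        self.loop = to_loop

    def _clamp(self, mv: int) -> int:
        c = self.cfg
        hi = c.amp_max_mv
        if c.strict_ceiling:
            hi = min(hi, self.ceiling_mv)
        return max(c.amp_min_mv, min(mv, hi))

    # ------------------------------------------------------------------
    def step(self, obs: Observation, dt: float) -> StimInput:
        """Advance ``dt`` seconds and return the stimulation now in force.

        AD detections act immediately (same control step); suppression is
        accumulated over the off phase; amplitude changes otherwise apply
        only at off->on cycle boundaries.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        c = self.cfg

        # after-discharge loop: immediate abort on a rising AD edge
        if obs.ad_detected and not self._prev_ad:
            self.amplitude_mv = self._clamp(
                self.amplitude_mv - c.decrement_mv)
            self.ceiling_mv = self.amplitude_mv
            self.phase = Phase.ABORTED
            self.phase_elapsed = 0.0
            self._adjusted_this_cycle = True
            self._log(Loop.AFTER_DISCHARGE)
        self._prev_ad = obs.ad_detected

        if self.phase in (Phase.OFF, Phase.ABORTED) and obs.suppression_detected:
            self._suppression_seen = True

        self.phase_elapsed += dt
        self.t += dt

        if self.phase is Phase.ON and self.phase_elapsed >= c.cycle_on - _EPS:
            self.phase = Phase.OFF
            self.phase_elapsed = 0.0
            self._suppression_seen = False
        elif (self.phase in (Phase.OFF, Phase.ABORTED)
              and self.phase_elapsed >= c.cycle_off - _EPS):
            # off->on boundary: pick the loop that governed this cycle
            if self._adjusted_this_cycle:
                # amplitude was already set by the AD abort; resume as-is
                self._adjusted_this_cycle = False
                self.phase = Phase.ON
                self.phase_elapsed = 0.0
                self._log(Loop.STIM_SEQUENCE)
            elif self._suppression_seen:
                self.phase = Phase.ON
                self.phase_elapsed = 0.0
                self._log(Loop.SUPPRESSION)
            else:
                self.amplitude_mv = self._clamp(
                    self.amplitude_mv + c.increment_mv)
                self.phase = Phase.ON
                self.phase_elapsed = 0.0
                self._log(Loop.RESTING)
            self._suppression_seen = False

        assert c.amp_min_mv <= self.amplitude_mv <= c.amp_max_mv, \
            "interlock violated"
        return StimInput(on=self.phase is Phase.ON,
                         amplitude=self.amplitude,
                         frequency=c.stim_frequency,
                         pulse_width=c.pulse_width)


class _HybridMode(str, Enum):
    CS = "CS"
    WAIT = "WAIT"
    DNE = "DNE"


class HybridController:
    """CS/DNE auto-shutoff program (externally prototyped control policy)."""

    def __init__(self, program: HybridProgram | None = None,
                 cfg: ControllerConfig | None = None,
                 detection_enabled: bool = True) -> None:
        self.program = program if program is not None else HybridProgram()
        self.cfg = cfg if cfg is not None else ControllerConfig(
            initial_amplitude=self.program.cs_amplitude)
        self.detection_enabled = detection_enabled
        self.mode = _HybridMode.CS
        self.phase = Phase.ON
        self.phase_elapsed = 0.0
        self.t = 0.0
        self._wait_elapsed = 0.0
        self._dne_done = 0
        self._prev_ad = False
        self.abort_times: list[float] = []

    @property
    def amplitude(self) -> float:
        if self.mode is _HybridMode.DNE:
            return self.program.dne_amplitude
        if self.mode is _HybridMode.WAIT:
            return 0.0
        return self.program.cs_amplitude

    def step(self, ad_detected: bool, dt: float) -> StimInput:
        if dt <= 0:
            raise ValueError("dt must be positive")
        c = self.cfg
        if (self.detection_enabled and ad_detected and not self._prev_ad
                and self.mode is not _HybridMode.WAIT):
            # halt stimulation within this control step, schedule DNE
            self.mode = _HybridMode.WAIT
            self.phase = Phase.ABORTED
            self._wait_elapsed = 0.0
            self.abort_times.append(self.t)
        self._prev_ad = ad_detected

        self.t += dt
        if self.mode is _HybridMode.WAIT:
            self._wait_elapsed += dt
            if self._wait_elapsed >= self.program.dne_delay - _EPS:
                self.mode = _HybridMode.DNE
                self.phase = Phase.ON
                self.phase_elapsed = 0.0
                self._dne_done = 0
        else:
            self.phase_elapsed += dt
            if self.phase is Phase.ON and self.phase_elapsed >= c.cycle_on - _EPS:
                self.phase = Phase.OFF
                self.phase_elapsed = 0.0
            elif (self.phase is Phase.OFF
                  and self.phase_elapsed >= c.cycle_off - _EPS):
                if self.mode is _HybridMode.DNE:
                    self._dne_done += 1
                    if self._dne_done >= self.program.dne_cycles:
                        self.mode = _HybridMode.CS
                self.phase = Phase.ON
                self.phase_elapsed = 0.0

        return StimInput(on=self.phase is Phase.ON,
                         amplitude=self.amplitude,
                         frequency=c.stim_frequency,
                         pulse_width=c.pulse_width)


# ----------------------------------------------------------------------
# trace validation
# ----------------------------------------------------------------------

@dataclass
class TraceReport:
    passed: bool
    diverged_at: int | None
    observed: list
    expected: list

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.passed:
            return f"trace OK ({len(self.observed)} entries)"
        i = self.diverged_at
        obs = self.observed[i] if i is not None and i < len(self.observed) else "<missing>"
        exp = self.expected[i] if i is not None and i < len(self.expected) else "<missing>"
        return f"trace FAIL at index {i}: observed {obs!r}, expected {exp!r}"


def validate_trace(observed, expected) -> TraceReport:
    """Exact sequence comparison with first-divergence reporting."""
    observed = list(observed)
    expected = list(expected)
    n = max(len(observed), len(expected))
    for i in range(n):
        if i >= len(observed) or i >= len(expected) or observed[i] != expected[i]:
            return TraceReport(False, i, observed, expected)
    return TraceReport(True, None, observed, expected)
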