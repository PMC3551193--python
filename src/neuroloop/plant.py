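"""Synthetic hippocampal network plant.

Generates LFP-like raw samples from a three-state latent network
(resting / suppressed / after-discharge) whose transitions are driven by
stimulation amplitude:

* moderate stimulation relaxes the beta-band envelope exponentially toward a
  suppressed level;
* high-amplitude stimulation probabilistically triggers an after-discharge
  (AD), a seizure-like high-energy episode whose duration grows with the
  pre-stimulation beta level;
* an AD left stimulated through an abort window becomes *sustained* — it
  outlasts its drawn duration until externally reset.  Aborting stimulation
  inside the window guarantees the AD runs out and terminates.

The emitted waveform is a 20 Hz tone whose band rms tracks the latent beta
envelope, plus broadband background noise, plus (while stimulating) an
artifact tone near 70 Hz whose amplitude scales with stimulation voltage.
All stochastic draws (AD induction at each stimulation onset, the sustain
draw at the abort-window boundary, per-sample noise) consume a single seeded
generator in that order, so trajectories are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Mode",
    "PlantParams",
    "PlantState",
    "StimInput",
    "ad_induction_probability",
    "ad_duration",
    "Plant",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Raised when a step duration is not an integer number of samples."""


class Mode(str, Enum):
    RESTING = "RESTING"
    SUPPRESSED = "SUPPRESSED"
    AD = "AD"


@dataclass
class PlantParams:
    """Calibration of the synthetic network.

    Amplitudes are beta-band rms values in microvolts; voltages are
    stimulation amplitudes at the electrode; times are seconds.
    """

    fs: float = 422.0
    beta_center: float = 20.0
    resting_beta_rms: float = 2.7
    ad_beta_rms: float = 30.0
    suppressed_beta_rms: float = 1.5
    ad_threshold_low: float = 1.5
    ad_threshold_certain: float = 1.7
    p_ad_at_low: float = 0.5
    p_sustain_uninterrupted: float = 1.0
    abort_window: float = 2.0
    ad_duration_min: float = 2.0
    ad_duration_gain: float = 1.0
    suppression_time_constant: float = 5.0
    full_suppression_amplitude: float = 1.25
    artifact_gain: float = 3.0
    artifact_freq: float = 70.0
    broadband_noise_rms: float = 0.5
    suppressed_mode_tol: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.suppressed_beta_rms < self.resting_beta_rms < self.ad_beta_rms):
            raise ValueError("require 0 < suppressed < resting < AD beta rms")
        if not (0 < self.ad_threshold_low <= self.ad_threshold_certain):
            raise ValueError("require 0 < ad_threshold_low <= ad_threshold_certain")
        if not (0.0 <= self.p_ad_at_low <= 1.0):
            raise ValueError("p_ad_at_low must lie in [0, 1]")
        if not (0.0 <= self.p_sustain_uninterrupted <= 1.0):
            raise ValueError("p_sustain_uninterrupted must lie in [0, 1]")
        for name in ("fs", "beta_center", "abort_window", "ad_duration_min",
                     "ad_duration_gain", "suppression_time_constant",
                     "full_suppression_amplitude", "artifact_gain",
                     "artifact_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.broadband_noise_rms < 0:
            raise ValueError("broadband_noise_rms must be non-negative")


@dataclass
class StimInput:
    """One stimulation setting: square biphasic pulses, 300 us width typical."""

    on: bool = False
    amplitude: float = 0.0  # volts
    frequency: float = 120.0  # Hz
    pulse_width: float = 300.0  # microseconds

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("stimulation amplitude must be >= 0")
        if self.frequency <= 0 or self.pulse_width <= 0:
            raise ValueError("frequency and pulse width must be > 0")


STIM_OFF = StimInput(on=False, amplitude=0.0)


@dataclass
class PlantState:
    """Snapshot of the latent network."""

    mode: Mode = Mode.RESTING
    beta_envelope: float = 2.7  # uVrms
    ad_remaining: float = 0.0  # seconds; 0 when no finite AD is pending
    ad_is_sustained: bool = False
    pre_stim_beta: float = 2.7  # uVrms at last stimulation onset
    clock: float = 0.0  # seconds


def ad_induction_probability(amplitude: float, params: PlantParams) -> float:
    """Probability that a stimulation onset at ``amplitude`` triggers an AD.

    Zero below ``ad_threshold_low``, one at or above ``ad_threshold_certain``,
    linear in between starting from ``p_ad_at_low`` at the lower threshold.
    Monotone non-decreasing everywhere.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    p = params
    if amplitude < p.ad_threshold_low:
        return 0.0
    if amplitude >= p.ad_threshold_certain:
        return 1.0
    span = p.ad_threshold_certain - p.ad_threshold_low
    frac = (amplitude - p.ad_threshold_low) / span
    return p.p_ad_at_low + (1.0 - p.p_ad_at_low) * frac


def ad_duration(pre_stim_beta: float, params: PlantParams) -> float:
    """Drawn AD duration (s): affine in pre-stim beta above the suppressed level."""
    if pre_stim_beta < 0:
        raise ValueError("pre_stim_beta must be >= 0")
    excess = max(0.0, pre_stim_beta - params.suppressed_beta_rms)
    return params.ad_duration_min + params.ad_duration_gain * excess


class Plant:
    """Stateful simulator; ``step`` advances time and emits raw samples."""

    def __init__(self, params: PlantParams | None = None,
                 seed: int | None = None) -> None:
        self.params = params if params is not None else PlantParams()
        if seed is None:
            seed = self.params.seed
        self.rng = np.random.default_rng(seed)
        p = self.params
        self.state = PlantState(beta_envelope=p.resting_beta_rms,
                                pre_stim_beta=p.resting_beta_rms)
        self._k = 0  # global sample counter
        self._prev_stim_on = False
        self._beta_phase = 0.0
        self._art_phase = 0.0
        # AD bookkeeping
        self._ad_active = False
        self._ad_onset = 0.0
        self._ad_duration = 0.0
        self._sustain_decided = False

    # ------------------------------------------------------------------
    @property
    def clock(self) -> float:
        return self._k / self.params.fs

    def reset_ad(self) -> None:
        """External reset of a (sustained) AD; envelope returns to resting."""
        self._ad_active = False
        self._sustain_decided = False
        self.state.ad_is_sustained = False
        self.state.ad_remaining = 0.0
        self.state.beta_envelope = self.params.resting_beta_rms
        self._refresh_mode(stim_on=False)

    # ------------------------------------------------------------------
    def step(self, stim: StimInput, dt: float,
             return_envelope: bool = False):
        """Advance ``dt`` seconds under constant stimulation ``stim``.

        ``dt`` must be an integer multiple of the sample period.  Returns the
        emitted raw samples (uV at fs); with ``return_envelope=True`` also
        returns the per-sample latent beta envelope.
        """
        p = self.params
        n_f = dt * p.fs
        n = round(n_f)
        if n <= 0 or abs(n_f - n) > 1e-6:
            raise AlignmentError(
                f"dt={dt} is not a positive integer multiple of 1/fs")

        st = self.state
        stim_on = bool(stim.on)

        # (a) stimulation onset: snapshot pre-stim beta and draw AD induction
        if stim_on and not self._prev_stim_on:
            st.pre_stim_beta = st.beta_envelope
            if not self._ad_active:
                prob = ad_induction_probability(stim.amplitude, p)
                draw = self.rng.random()
                if draw < prob:
                    self._ad_active = True
                    self._sustain_decided = False
                    st.ad_is_sustained = False
                    self._ad_onset = self.clock
                    self._ad_duration = ad_duration(st.pre_stim_beta, p)
                    st.beta_envelope = p.ad_beta_rms
        self._prev_stim_on = stim_on

        # (c) stimulation removed inside the abort window: AD will terminate
        if self._ad_active and not self._sustain_decided and not stim_on:
            self._sustain_decided = True
            st.ad_is_sustained = False

        out = np.empty(n)
        env_out = np.empty(n) if return_envelope else None
        filled = 0
        while filled < n:
            seg_end_t = (self._k + (n - filled)) / p.fs
            # next internal event inside (clock, seg_end_t]
            events = []
            if self._ad_active:
                if not self._sustain_decided and stim_on:
                    events.append(self._ad_onset + p.abort_window)
                if not st.ad_is_sustained:
                    events.append(self._ad_onset + self._ad_duration)
            t_now = self.clock
            pending = [t for t in events if t > t_now + 1e-12]
            t_ev = min(pending) if pending else math.inf
            if t_ev >= seg_end_t - 1e-12:
                m = n - filled
            else:
                m = max(1, math.ceil((t_ev - t_now) * p.fs - 1e-9))
                m = min(m, n - filled)
            x, env = self._synth(m, stim_on, stim.amplitude)
            out[filled:filled + m] = x
            if return_envelope:
                env_out[filled:filled + m] = env
            filled += m
            self._k += m
            # handle events whose time has now been reached
            if self._ad_active:
                t_now = self.clock
                if (not self._sustain_decided and stim_on
                        and t_now >= self._ad_onset + p.abort_window - 1e-9):
                    # stimulation ran uninterrupted through the abort window
                    self._sustain_decided = True
                    st.ad_is_sustained = (
                        self.rng.random() < p.p_sustain_uninterrupted)
                if (not st.ad_is_sustained
                        and t_now >= self._ad_onset + self._ad_duration - 1e-9):
                    # finite AD runs out at its drawn duration
                    self._sustain_decided = True
                    self._ad_active = False

        st.clock = self.clock
        if self._ad_active and not st.ad_is_sustained:
            st.ad_remaining = max(0.0, self._ad_onset + self._ad_duration
                                  - self.clock)
        else:
            st.ad_remaining = 0.0
        self._refresh_mode(stim_on)
        if return_envelope:
            return out, env_out
        return out

    # ------------------------------------------------------------------
    def _synth(self, m: int, stim_on: bool, amplitude: float):
        """Emit ``m`` samples under the current (constant) regime."""
        p = self.params
        st = self.state
        tk = np.arange(1, m + 1) / p.fs
        if self._ad_active:
            env = np.full(m, p.ad_beta_rms)
        else:
            if stim_on:
                # graded suppression: depth grows with amplitude, full by
                # the decreased-network-excitability level (1.25 V default)
                depth = min(1.0, amplitude / p.full_suppression_amplitude)
                target = (p.resting_beta_rms
                          - (p.resting_beta_rms - p.suppressed_beta_rms)
                          * depth)
            else:
                target = p.resting_beta_rms
            env = target + (st.beta_envelope - target) * np.exp(
                -tk / p.suppression_time_constant)
        st.beta_envelope = float(env[-1])

        phases = self._beta_phase + 2.0 * np.pi * p.beta_center * tk
        self._beta_phase = float(phases[-1] % (2.0 * np.pi))
        x = env * math.sqrt(2.0) * np.sin(phases)
        if p.broadband_noise_rms > 0:
            x = x + self.rng.normal(0.0, p.broadband_noise_rms, m)
        if stim_on and amplitude > 0:
            aph = self._art_phase + 2.0 * np.pi * p.artifact_freq * tk
            self._art_phase = float(aph[-1] % (2.0 * np.pi))
            x = x + p.artifact_gain * amplitude * np.sin(aph)
        return x, env

    def _refresh_mode(self, stim_on: bool) -> None:
        p = self.params
        st = self.state
        if self._ad_active:
            st.mode = Mode.AD
        elif (abs(st.beta_envelope - p.suppressed_beta_rms)
              <= p.suppressed_mode_tol * p.suppressed_beta_rms):
            st.mode = Mode.SUPPRESSED
        else:
            st.mode = Mode.RESTING
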