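"""Experiment orchestration: titration sweeps, trials, validation, recording.

Everything in this module drives the full simulated stack — plant, sensing
chain, detector, control policy and (optionally) the telemetry link — to
reproduce the study workflows:

* :func:`run_titration` sweeps stimulation amplitude/frequency and tabulates
  the network transfer function (beta band power during vs between
  stimulation, AD occurrence);
* :func:`run_open_loop_trial` applies cycle stimulation (CS, 1.50 V) with
  detection disabled and scores sustained after-discharges from plant ground
  truth;
* :func:`run_closed_loop_trial` closes the loop through either the embedded
  detector (one 5 Hz step from detection to abort) or the hybrid telemetry
  path, and scores the same outcome;
* :func:`run_embedded_validation` replays a scripted detection schedule
  through the embedded titration policy and checks the commanded amplitude
  path exactly;
* :func:`record_event` / :class:`StorageModel` emulate the device's
  event-triggered 8-s loop recordings and its bounded SRAM file system.

Every run is reproducible from (config, seed): all child generators are
spawned from one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (EVENT, NON_EVENT, DurationConstraints, LabeledSegment,
                         LinearBoundary, StreamingDetector, train_fisher)
from .control_policy import (ControllerConfig, EmbeddedController,
                             HybridProgram, Observation, Phase, TraceReport,
                             validate_trace)
from .hybrid_link import DeviceReceiver, LinkConfig, TelemetryLink
from .plant import Plant, PlantParams, StimInput
from .signal_chain import (BIOMARKER_BETA, STIM_ENERGY, PowerChannelConfig,
                           StreamingPowerChannel, TimeChannelConfig,
                           sense_time)

__all__ = [
    "EventRecord",
    "StorageModel",
    "StorageFullError",
    "TrialSummary",
    "record_event",
    "train_ad_classifier",
    "train_suppression_classifier",
    "run_titration",
    "run_open_loop_trial",
    "run_closed_loop_trial",
    "run_embedded_validation",
    "default_validation_script",
    "FEATURE_LABELS",
]

FEATURE_LABELS = [BIOMARKER_BETA.label, STIM_ENERGY.label]


# ----------------------------------------------------------------------
# device file-system emulation
# ----------------------------------------------------------------------

class StorageFullError(RuntimeError):
    """Embedded record storage is full and the policy rejects new writes."""


@dataclass
class EventRecord:
    """One event-triggered loop recording with embedded metadata."""

    trigger: str  # timer | embedded_classifier | button | scripted
    t_event: float
    samples: np.ndarray  # (channels, n)
    duration: float = 8.0
    channels: int = 2
    fs: float = 422.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        expect = (self.channels, round(self.duration * self.fs))
        if self.samples.shape != expect:
            raise ValueError(
                f"samples shape {self.samples.shape} != expected {expect}")


@dataclass
class StorageModel:
    """Bounded embedded record store (~200 recordings of SRAM)."""

    capacity_records: int = 200
    policy: str = "reject"  # or "ring"
    records: list = field(default_factory=list)

    @property
    def used(self) -> int:
        return len(self.records)

    def add(self, record: EventRecord) -> None:
        if self.used >= self.capacity_records:
            if self.policy == "reject":
                raise StorageFullError(
                    f"storage full ({self.capacity_records} records); "
                    "download and clear first")
            self.records.pop(0)
        self.records.append(record)

    def clear(self) -> list:
        out, self.records = self.records, []
        return out


def record_event(trigger: str, t_event: float, raw: np.ndarray,
                 storage: StorageModel, t0: float = 0.0, fs: float = 422.0,
                 pre: float = 4.0, post: float = 4.0,
                 meta: dict | None = None) -> EventRecord:
    """Capture the loop-recording segment around a trigger and store it.

    ``raw`` is the full (channels, n) session waveform starting at ``t0``;
    the captured segment spans [t_event - pre, t_event + post).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    duration = pre + post
    start = round((t_event - pre - t0) * fs)
    n = round(duration * fs)
    if start < 0 or start + n > raw.shape[1]:
        raise ValueError("trigger window outside the available recording")
    seg = raw[:, start:start + n]
    rec = EventRecord(
        trigger=trigger, t_event=t_event, samples=seg, duration=duration,
        channels=raw.shape[0], fs=fs,
        meta={"event_type": trigger, "t_event": t_event,
              "t_start": t_event - pre, "t_stop": t_event + post,
              **(meta or {})})
    storage.add(rec)
    return rec


# ----------------------------------------------------------------------
# closed-loop plumbing
# ----------------------------------------------------------------------

def _chunk_sizes(fs: float, n_ticks: int, rate: float = 5.0):
    """Per-tick sample counts so power-channel outputs land on the 0.2 s grid."""
    step = fs / rate
    idx = [round(k * step) for k in range(n_ticks + 1)]
    return [idx[k + 1] - idx[k] for k in range(n_ticks)]


class _SensedChain:
    """Time-channel noise plus the two default power channels, streaming."""

    def __init__(self, params: PlantParams, noise_rng: np.random.Generator,
                 lsb_scale: float = 1.0) -> None:
        self.tc = TimeChannelConfig(fs=params.fs)
        self.noise_rng = noise_rng
        self.bio = StreamingPowerChannel(PowerChannelConfig(
            band=BIOMARKER_BETA, fs_in=params.fs, lsb_scale=lsb_scale))
        self.se = StreamingPowerChannel(PowerChannelConfig(
            band=STIM_ENERGY, fs_in=params.fs, lsb_scale=lsb_scale))

    def process(self, raw: np.ndarray, stim_on: bool):
        sensed = sense_time(raw, self.tc, stim_on, rng=self.noise_rng)
        b = self.bio.process(sensed, stim_on)
        s = self.se.process(sensed, stim_on)
        feats = [np.array([bb.value_lsb, ss.value_lsb], dtype=float)
                 for bb, ss in zip(b, s)]
        ts = [bb.t for bb in b]
        return sensed, feats, ts


# ----------------------------------------------------------------------
# classifier training on plant-generated data
# ----------------------------------------------------------------------

def _power_features(plant: Plant, chain: _SensedChain, stim: StimInput,
                    seconds: float) -> np.ndarray:
    ticks = round(seconds * 5)
    feats = []
    for n in _chunk_sizes(plant.params.fs, ticks):
        raw = plant.step(stim, n / plant.params.fs)
        _, fs_, _ = chain.process(raw, stim.on)
        feats.extend(fs_)
    return np.array(feats)


def train_ad_classifier(seed: int | None = 0,
                        params: PlantParams | None = None,
                        constraints: DurationConstraints | None = None):
    """Train the AD-vs-rest boundary on plant-generated labeled recordings.

    Produces EVENT segments from induced ADs at 1.8 V (stimulation on, so
    the stimulation-energy feature is exercised) and NON_EVENT segments from
    resting and stimulated-suppression runs.  The first second of every
    segment is discard-masked as settling transient.
    """
    params = params if params is not None else PlantParams()
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(6)
    ev_segs, ne_segs = [], []

    def _seg(plant, chain, stim, seconds, label, source, discard_s=1.0):
        x = _power_features(plant, chain, stim, seconds)
        mask = np.zeros(len(x), dtype=bool)
        mask[:round(discard_s * 5)] = True
        return LabeledSegment(x, label, discard_mask=mask, source=source)

    # resting background
    plant = Plant(params, seed=kids[0])
    chain = _SensedChain(params, np.random.default_rng(kids[1]))
    ne_segs.append(_seg(plant, chain, StimInput(False, 0.0), 30.0,
                        NON_EVENT, "resting"))
    # stimulated suppression (artifact present, no AD)
    plant = Plant(params, seed=kids[2])
    chain = _SensedChain(params, np.random.default_rng(kids[3]))
    ne_segs.append(_seg(plant, chain, StimInput(True, 1.25), 30.0,
                        NON_EVENT, "suppression_stim"))
    # induced ADs at a certainly-inducing amplitude
    plant = Plant(params, seed=kids[4])
    chain = _SensedChain(params, np.random.default_rng(kids[5]))
    for i in range(3):
        # settle at rest, then stimulate above the certain threshold
        _power_features(plant, chain, StimInput(False, 0.0), 4.0)
        ev_segs.append(_seg(plant, chain, StimInput(True, 1.8), 8.0,
                            EVENT, f"ad_{i}"))
        plant.reset_ad()
    boundary = train_fisher(ev_segs, ne_segs, feature_labels=FEATURE_LABELS)
    return boundary, (constraints or DurationConstraints()), ev_segs, ne_segs


def train_suppression_classifier(seed: int | None = 0,
                                 params: PlantParams | None = None):
    """Suppression-vs-resting boundary on the biomarker-beta feature alone."""
    params = params if params is not None else PlantParams()
    ss = np.random.SeedSequence([1, seed if seed is not None else 0])
    kids = ss.spawn(4)
    ev_segs, ne_segs = [], []
    for i, (label, stim, bucket) in enumerate([
            (EVENT, StimInput(True, 1.25), ev_segs),
            (NON_EVENT, StimInput(False, 0.0), ne_segs)]):
        plant = Plant(params, seed=kids[2 * i])
        chain = _SensedChain(params, np.random.default_rng(kids[2 * i + 1]))
        if label == EVENT:  # drive the plant into suppression first
            plant.step(StimInput(True, 1.25),
                       round(6 * params.suppression_time_constant
                             * params.fs) / params.fs)
        x = _power_features(plant, chain, stim, 60.0)[:, :1]
        # chunk into 10 s segments so segment-level CV has folds to split
        for j in range(0, len(x), 50):
            seg = x[j:j + 50]
            if len(seg) < 10:
                continue
            mask = np.zeros(len(seg), dtype=bool)
            if j == 0:
                mask[:10] = True
            bucket.append(LabeledSegment(seg, label,
                                         discard_mask=mask,
                                         source=f"{label.lower()}_{j // 50}"))
    boundary = train_fisher(ev_segs, ne_segs,
                            feature_labels=[BIOMARKER_BETA.label])
    return boundary, ev_segs, ne_segs


# ----------------------------------------------------------------------
# titration sweep
# ----------------------------------------------------------------------

def run_titration(amplitudes, frequencies=(50.0, 120.0), cycles: int = 1,
                  seed: int | None = 0, params: PlantParams | None = None,
                  cycle_on: float = 25.0, cycle_off: float = 25.0,
                  settle: float = 2.0) -> pd.DataFrame:
    """Transfer-function sweep: beta band power during vs between stimulation.

    One fresh, seeded plant per (amplitude, frequency) condition; a sustained
    AD is externally reset at the end of a cycle, mirroring experimenter
    intervention.  ``settle`` seconds after each stimulation transition are
    excluded from the means.
    """
    params = params if params is not None else PlantParams()
    ss = np.random.SeedSequence([2, seed if seed is not None else 0])
    rows = []
    for amp in amplitudes:
        for freq in frequencies:
            k_plant, k_noise = ss.spawn(2)
            plant = Plant(params, seed=k_plant)
            chain = _SensedChain(params, np.random.default_rng(k_noise))
            during, between = [], []
            ad_occurred = False
            for _ in range(cycles):
                stim = StimInput(True, amp, frequency=freq) if amp > 0 \
                    else StimInput(False, 0.0)
                x_on = _power_features(plant, chain, stim, cycle_on)
                ad_occurred |= plant.state.mode.value == "AD"
                x_off = _power_features(plant, chain, StimInput(False, 0.0),
                                        cycle_off)
                ad_occurred |= plant.state.ad_is_sustained
                skip = round(settle * 5)
                during.extend(x_on[skip:, 0])
                between.extend(x_off[skip:, 0])
                if plant.state.ad_is_sustained:
                    plant.reset_ad()
            rows.append({"amplitude": amp, "frequency": freq,
                         "mean_beta_power_during_stim": float(np.mean(during)),
                         "mean_beta_power_between_stim": float(np.mean(between)),
                         "ad_occurred": bool(ad_occurred),
                         "n_cycles": cycles})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# open- and closed-loop trials
# ----------------------------------------------------------------------

@dataclass
class TrialSummary:
    n_trials: int
    n_sustained_ad: int
    mode: str
    seed: int | None
    detection_latencies: list = field(default_factory=list)

    @property
    def fraction_sustained(self) -> float:
        return self.n_sustained_ad / self.n_trials


def run_open_loop_trial(n: int, seed: int | None = 0,
                        params: PlantParams | None = None,
                        program: HybridProgram | None = None,
                        cycle_on: float = 25.0) -> TrialSummary:
    """n independent CS deliveries with detection disabled (never aborted)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params if params is not None else PlantParams()
    program = program if program is not None else HybridProgram()
    ss = np.random.SeedSequence([3, seed if seed is not None else 0])
    kids = ss.spawn(n)
    sustained = 0
    stim = StimInput(True, program.cs_amplitude)
    dt = round(cycle_on * params.fs) / params.fs
    for k in kids:
        plant = Plant(params, seed=k)
        plant.step(stim, dt)
        if plant.state.ad_is_sustained:
            sustained += 1
    return TrialSummary(n_trials=n, n_sustained_ad=sustained,
                        mode="open_loop", seed=seed)


def _closed_loop_delivery(plant: Plant, chain: _SensedChain,
                          detector: StreamingDetector,
                          program: HybridProgram, mode: str,
                          link_cfgs=None, link_rng=None,
                          pre_roll: float = 3.0,
                          max_on: float = 25.0):
    """One CS delivery under the detect-and-abort program.

    Returns (sustained, detection_latency_or_None).  In embedded mode the
    abort takes effect on the control step after detection (one 5 Hz
    sample); in hybrid mode features travel up the link, the external policy
    detects, and the abort command travels back down.
    """
    p = plant.params
    fs = p.fs
    stim_cmd = StimInput(False, 0.0)
    uplink = downlink = receiver = None
    if mode == "hybrid":
        up_cfg, down_cfg = link_cfgs
        uplink = TelemetryLink(up_cfg, rng=link_rng)
        downlink = TelemetryLink(down_cfg, rng=link_rng)
        receiver = DeviceReceiver(down_cfg, amp_max=1.7)

    pre_ticks = round(pre_roll * 5)
    total_ticks = pre_ticks + round((max_on + p.abort_window + 2.0) * 5)
    sizes = _chunk_sizes(fs, total_ticks)
    t_onset = pre_ticks / 5.0
    detect_t = None
    aborted = False
    t = 0.0
    for tick, nsmp in enumerate(sizes):
        if mode == "hybrid":
            # device applies whatever command is in force right now
            for msg in downlink.poll(t):
                receiver.receive(msg, t)
            cmd = receiver.command_in_force(t)
            stim_now = cmd if tick >= pre_ticks else StimInput(False, 0.0)
            if tick == pre_ticks:
                # CS delivery starts: device pre-programmed CS amplitude
                receiver.current = StimInput(True, program.cs_amplitude)
                receiver.last_valid_t = t
                stim_now = receiver.current
        else:
            if tick < pre_ticks:
                stim_now = StimInput(False, 0.0)
            elif aborted or t >= t_onset + max_on:
                stim_now = StimInput(False, 0.0)
            else:
                stim_now = StimInput(True, program.cs_amplitude)
        raw = plant.step(stim_now, nsmp / fs)
        _, feats, ts = chain.process(raw, stim_now.on)
        for x, tf in zip(feats, ts):
            if mode == "hybrid":
                uplink.transmit(x, tf)
            else:
                detector.update(x, tf)
                if detector.detected and not aborted:
                    aborted = True
                    detect_t = tf
        if mode == "hybrid":
            for msg in uplink.poll(t):
                if not msg.valid:
                    continue
                detector.update(msg.payload, t)
                if detector.detected and not aborted:
                    aborted = True
                    detect_t = t
                    downlink.transmit(StimInput(False, 0.0), t)
        t += nsmp / fs
        # stop once the sustain question is settled and stim is off
        if (t > t_onset + p.abort_window + 1.0
                and (aborted or not plant.state.mode.value == "AD"
                     or plant.state.ad_is_sustained)):
            break
    latency = None if detect_t is None else detect_t - t_onset
    return plant.state.ad_is_sustained, latency


def run_closed_loop_trial(n: int, boundary: LinearBoundary,
                          constraints: DurationConstraints | None = None,
                          mode: str = "embedded", seed: int | None = 0,
                          params: PlantParams | None = None,
                          program: HybridProgram | None = None,
                          link_cfg: LinkConfig | None = None) -> TrialSummary:
    """n CS deliveries with the detect-and-abort algorithm enabled."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("embedded", "hybrid"):
        raise ValueError("mode must be 'embedded' or 'hybrid'")
    params = params if params is not None else PlantParams()
    program = program if program is not None else HybridProgram()
    constraints = constraints or DurationConstraints()
    if mode == "hybrid" and link_cfg is None:
        link_cfg = LinkConfig()
    ss = np.random.SeedSequence([4, seed if seed is not None else 0])
    sustained = 0
    latencies = []
    for _ in range(n):
        k_plant, k_noise, k_link = ss.spawn(3)
        plant = Plant(params, seed=k_plant)
        chain = _SensedChain(params, np.random.default_rng(k_noise))
        detector = StreamingDetector(boundary, constraints)
        link_cfgs = (link_cfg, link_cfg) if mode == "hybrid" else None
        s, lat = _closed_loop_delivery(
            plant, chain, detector, program, mode,
            link_cfgs=link_cfgs,
            link_rng=np.random.default_rng(k_link))
        sustained += int(s)
        if lat is not None:
            latencies.append(lat)
    return TrialSummary(n_trials=n, n_sustained_ad=sustained,
                        mode=f"closed_loop_{mode}", seed=seed,
                        detection_latencies=latencies)


# ----------------------------------------------------------------------
# embedded validation replay
# ----------------------------------------------------------------------

def default_validation_script():
    """Scripted detection schedule exercising all three control loops.

    Cycle labels and the expected commanded-amplitude path (mV) at each ON
    start: start at 1.7 V; an AD aborts and drops to 1.6 V; suppression
    holds; two resting cycles climb 1.65 then 1.7 V; a final AD drops back
    to 1.6 V.
    """
    schedule = ["ad", "suppression", "none", "none", "ad"]
    expected_mv = [1700, 1600, 1600, 1650, 1700, 1600]
    return schedule, expected_mv


def run_embedded_validation(schedule=None, expected_mv=None,
                            cfg: ControllerConfig | None = None,
                            dt: float = 0.2):
    """Replay a scripted per-cycle detection schedule through the controller.

    Returns (controller, on_amplitudes_mv, TraceReport).
    """
    if schedule is None:
        schedule, expected_mv = default_validation_script()
    cfg = cfg if cfg is not None else ControllerConfig(initial_amplitude=1.7)
    ctrl = EmbeddedController(cfg)
    on_amps = [ctrl.amplitude_mv]
    k = 0
    ad_pending = schedule[0] == "ad" if schedule else False
    supp_pending = schedule[0] == "suppression" if schedule else False
    t_guard = (len(schedule) + 2) * (cfg.cycle_on + cfg.cycle_off) * 2
    while k < len(schedule):
        obs = Observation()
        if (ctrl.phase is Phase.ON and ad_pending
                and ctrl.phase_elapsed >= cfg.cycle_on / 5):
            obs = Observation(ad_detected=True)
            ad_pending = False
        elif (ctrl.phase in (Phase.OFF, Phase.ABORTED) and supp_pending
                and ctrl.phase_elapsed >= cfg.cycle_off / 5):
            obs = Observation(suppression_detected=True)
            supp_pending = False
        prev = ctrl.phase
        ctrl.step(obs, dt)
        if ctrl.phase is Phase.ON and prev is not Phase.ON:
            on_amps.append(ctrl.amplitude_mv)
            k += 1
            if k < len(schedule):
                ad_pending = schedule[k] == "ad"
                supp_pending = schedule[k] == "suppression"
        if ctrl.t > t_guard:  # pragma: no cover - defensive
            raise RuntimeError("validation replay did not terminate")
    report = (validate_trace(on_amps, expected_mv)
              if expected_mv is not None
              else TraceReport(True, None, on_amps, []))
    return ctrl, on_amps, report
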