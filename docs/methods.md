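# Methods

This note documents the models, defaults and design choices behind
`neuroloop`, and what the simulated studies do and do not demonstrate.

## The synthetic plant

The plant is a phenomenological, not biophysical, model of a stimulated
hippocampal network. It reduces the network to one latent variable — the
beta-band envelope (µVrms) — plus a three-way mode label (resting,
suppressed, after-discharge) and a small set of stochastic rules:

- **Envelope dynamics.** Outside an AD, the envelope relaxes exponentially
  (`suppression_time_constant`, default 5 s) toward a target: the resting
  level (2.7 µVrms) with stimulation off, or a suppression target with
  stimulation on. Suppression depth is graded with amplitude and saturates
  at `full_suppression_amplitude` (1.25 V, the DNE level), where the target
  equals the suppressed level (1.5 µVrms). The graded depth is what gives
  the transfer-function sweep its characteristic shape: during-stimulation
  beta power falls monotonically over 0.75–1.25 V, then AD induction takes
  over at ≥ 1.5 V.
- **AD induction** is evaluated once per stimulation *onset* (off→on
  transition), not per pulse: zero below 1.5 V, certain at ≥ 1.7 V, linear
  from `p_ad_at_low` (0.5) between. The 0.5 boundary value makes a single
  open-loop 1.50 V delivery end in a sustained AD half the time, which is
  the open-loop reference condition.
- **AD duration** is affine in the pre-stimulation beta excess over the
  suppressed baseline: minimum 2 s plus 1 s per µVrms. Only the
  monotone-increasing relationship is meaningful; the gain is a calibration
  choice.
- **Sustain rule.** An AD becomes sustained (outlasting its drawn duration
  until externally reset) with probability `p_sustain_uninterrupted`
  (default 1) if stimulation continues through the 2 s `abort_window`;
  switching stimulation off inside the window guarantees termination. This
  operationalization makes the open-loop/closed-loop contrast a direct
  consequence of detection-and-abort latency.
- **Waveform synthesis.** A single 20 Hz tone scaled so its band rms equals
  the envelope, white broadband noise (0.5 µVrms), and, during stimulation,
  a 70 Hz artifact tone of `artifact_gain × amplitude` µV peak. A tone plus
  white noise is the simplest signal for which the 20 ± 2.5 Hz band-power
  chain is meaningful; there is no 1/f background, no phase structure and
  no non-stationarity beyond the envelope itself.

All stochastic draws (induction, sustain, noise) consume one seeded
generator in a fixed order, so any trajectory is exactly reproducible from
(parameters, seed, stimulation sequence). Step durations must be integer
multiples of the 1/422 s sample period; misaligned requests raise rather
than silently resample.

## Sensing chain

Time channels add white input-referred noise at the device floors
(150/300 nV/√Hz without/with stimulation), realized as per-sample noise of
rms `floor × √(fs/2)`. Power channels replace the device's analog
band-power circuit with a functionally equivalent digital chain:
order-4 Butterworth band-pass → square → order-2 low-pass at 2 Hz →
decimation onto the exact 0.2 s output grid → round-half-away-from-zero
quantization with saturation. The filter orders were chosen so the chain
settles in under a second, keeping total embedded detection latency near
two output samples. For a pure in-band tone of rms *r* the steady-state
output is `round(r²/lsb_scale)`; `lsb_scale` defaults to 1 µV² per LSB so
the suppressed→AD swing spans ~900 LSB while the suppressed baseline sits
at ~2 LSB — the scale is arbitrary (as LSB units are) but consistent
within a run. Because 422/5 is not an integer, output sample *k* is taken
at input index `round(k·422/5)`; the output cadence is exactly 0.2 s
regardless of chunking.

A consequence of the noise model worth knowing: the measured band rms of a
state is `√(state² + floor²·B)` with B = 5 Hz the biomarker bandwidth. At
the stimulation-on floor this adds ~0.45 µV² and the suppressed state reads
≈ 1.62 µVrms rather than 1.5 — an ~8 % measurement-noise bias that is a
property of the sensing contract, not an error.

## Classifier

Training is a ridge-regularized Fisher discriminant,
`w ∝ (S_w + λI)⁻¹(m₁ − m₀)` with λ defaulting to 10⁻³ of the mean scatter
diagonal, and the bias at the midpoint of the projected class means. A
margin of exactly zero classifies as non-event (the conservative side).
The default feature space is {biomarker-beta LSB, stim-energy LSB}; the
stimulation-energy channel is included deliberately so events remain
separable while stimulation artifact is present. Tapped-delay augmentation
is available but off by default. Reports (margin histograms, TP/FP sweeps,
segment-level 5-fold cross-validation that never splits within a recording)
let a user move the operating point by retuning the threshold on the margin
axis.

Duration constraints trade latency for specificity: onset_count = 1
(assert on the first event-side 5 Hz sample, 200 ms) and
termination_count = 5 (1 s clear hysteresis) by default. Margins are
computed in floating point; the integer arithmetic of a real embedded
implementation is not modeled.

## Control policies

The embedded titration machine holds amplitude in integer millivolts
(repeated ±50/100 mV steps can never accumulate floating-point drift) and
clamps every command into the `[amp_min, amp_max]` interlock. Detections
are evaluated every control step; amplitude changes apply at off→on cycle
boundaries except the AD abort, which is immediate. After an abort, the
next cycle resumes at the decremented amplitude without a resting-loop
increment — the decrement *was* that cycle's adjustment. The ceiling set by
an AD abort is advisory by default (the resting loop may re-probe past it,
up to `amp_max`, to verify it is still valid); `strict_ceiling=True` makes
it binding. When several observations coincide the priority is
AD > suppression > resting — safety first. Cycle durations default to
25 s on / 25 s off; "one cycle" means one on+off period (50 s) everywhere.

The hybrid CS/DNE program halts stimulation on the control step where an AD
is detected, waits `dne_delay` (default 5 s — a programmed delay with no
canonical value), delivers `dne_cycles` (1) cycles at 1.25 V and returns to
1.50 V cycling. An AD during the DNE cycle re-triggers the same rule.

## Telemetry link

The external loop's channel is modeled as a contract: per-direction latency
drawn from a log-normal with median 0.5 s, hard-capped at 1.0 s
(`latency_sigma` 0.3), in-order delivery, optional per-message drop and
corruption, and a device failsafe reverting to the safe pre-programmed
state after 5 s without a valid command. Integrity checking is a validity
flag — detection-and-rejection is the contract; no checksum polynomial is
computed. Commands outside the amplitude interlock are rejected and logged,
never raised. Note that the worst-case round trip (~2.0 s) plus the ~0.4 s
detection-chain latency can exceed the plant's 2.0 s abort window: hybrid
closed-loop operation collapses the sustained-AD rate but does not
guarantee zero, whereas the embedded mode (one 5 Hz step from detection to
abort) does. That latency contrast is the point of embedding.

## Study sizes and numerical choices

- Open-/closed-loop trials use n = 400 independent deliveries so the
  binomial 95 % CI on a 0.5 fraction is ±4.9 points; each trial spawns its
  own child seed from one `SeedSequence`, making summaries reproducible
  and trials independent.
- Closed-loop trials simulate ~3 s of pre-roll (filter settling and
  baseline) plus the delivery until the abort window has resolved; open-loop
  trials simulate the full 25 s on-phase (the off-phase cannot change the
  sustained outcome and is omitted).
- The titration sweep discards 2 s after each stimulation transition before
  averaging band power, and resets a sustained AD at cycle end, mirroring
  experimenter intervention.
- Band rms measurements use a Hann-windowed periodogram integrated over the
  band; 60 s records give a 1/60 Hz resolution, ample for a 5 Hz band.
- Quantization is round-half-away-from-zero with saturation at a
  configurable full scale (default 65535 LSB).

## Limitations

The plant is a calibration target, not a disease model: it has no
biophysics, no second (thalamic) node, no circadian or medication drift
(the resting loop exists to counteract such drift, but no drift model is
parameterized), no accelerometer channel, and its AD statistics are
memoryless per onset. Passing the simulated studies demonstrates that the
detection and control logic meet their latency and titration contracts
under the stated calibration — it says nothing about classifier performance
on real LFP, where artifacts, non-stationarity and label noise dominate.
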