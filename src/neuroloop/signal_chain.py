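"""Implanted-device sensing path emulation.

Two kinds of channel mirror the device front end:

* **time channels** — full-rate (422 Hz) waveforms with an input-referred
  white noise floor of 150 nV/rtHz while not stimulating and 300 nV/rtHz
  while stimulating;
* **power channels** — band-limited spectral power, down-sampled to 5 Hz and
  quantized to an arbitrary integer unit (LSB).

The device's analog band-power circuit is emulated by an equivalent digital
chain: recursive band-pass (Butterworth, order 4) -> square -> low-pass
smoothing (order 2, 2 Hz corner) -> decimation onto an exact 0.2 s grid ->
integer quantization.  For a pure in-band tone of rms r the steady-state
output is round(r^2 / lsb_scale).

A streaming variant (:class:`StreamingPowerChannel`) carries filter state
across chunks so the closed-loop controllers can consume power samples in
real time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "TimeChannelConfig",
    "BandSpec",
    "PowerChannelConfig",
    "PowerSample",
    "BIOMARKER_BETA",
    "BROAD_BETA",
    "STIM_ENERGY",
    "sense_time",
    "StreamingPowerChannel",
    "band_power",
    "rms_in_band",
]

POWER_RATE = 5.0  # Hz, fixed output cadence of every power channel


@dataclass
class TimeChannelConfig:
    """Time-channel sensing configuration; noise floors in nV/rtHz."""

    fs: float = 422.0
    noise_floor_no_stim: float = 150.0
    noise_floor_stim: float = 300.0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_floor_no_stim < 0 or self.noise_floor_stim < 0:
            raise ValueError("noise floors must be non-negative")
        if self.noise_floor_stim < self.noise_floor_no_stim:
            raise ValueError("stim-on noise floor must be >= stim-off floor")


@dataclass(frozen=True)
class BandSpec:
    lo: float
    hi: float
    label: str

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("require 0 < lo < hi")


BIOMARKER_BETA = BandSpec(17.5, 22.5, "biomarker_beta")  # 20 +- 2.5 Hz
BROAD_BETA = BandSpec(10.0, 30.0, "broad_beta")
STIM_ENERGY = BandSpec(65.0, 75.0, "stim_energy")  # ~70 Hz stimulation energy


@dataclass
class PowerChannelConfig:
    band: BandSpec = BIOMARKER_BETA
    fs_in: float = 422.0
    output_rate: float = POWER_RATE
    lsb_scale: float = 1.0  # uV^2 (band power) per LSB
    bp_order: int = 4
    smooth_hz: float = 2.0
    full_scale: int = 65535

    def __post_init__(self) -> None:
        if self.output_rate != POWER_RATE:
            raise ValueError("power channels emit at exactly 5 Hz")
        if self.lsb_scale <= 0:
            raise ValueError("lsb_scale must be positive")
        if not (self.band.hi < self.fs_in / 2):
            raise ValueError("band edges incompatible with sampling rate")


@dataclass(frozen=True)
class PowerSample:
    t: float
    value_lsb: int
    band: str
    stim_on: bool


def sense_time(samples: np.ndarray, cfg: TimeChannelConfig,
               stim_on: np.ndarray | bool = False,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> np.ndarray:
    """Add input-referred front-end noise to a raw waveform.

    The applicable noise floor (stim on/off, per sample) is realized as white
    noise with per-sample rms ``floor * sqrt(fs / 2)`` so that its one-sided
    spectral density equals the floor.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input samples must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)
    flags = np.broadcast_to(np.asarray(stim_on, dtype=bool), x.shape)
    floor_uv = np.where(flags, cfg.noise_floor_stim,
                        cfg.noise_floor_no_stim) * 1e-3  # nV -> uV per rtHz
    sigma = floor_uv * math.sqrt(cfg.fs / 2.0)
    if np.all(sigma == 0):
        return x.copy()
    return x + rng.normal(0.0, 1.0, x.shape) * sigma


class StreamingPowerChannel:
    """Stateful band-power extractor emitting on the exact 0.2 s grid.

    Output sample k corresponds to input index round(k * fs / 5); chunk
    boundaries are invisible to the output.
    """

    def __init__(self, cfg: PowerChannelConfig | None = None) -> None:
        self.cfg = cfg if cfg is not None else PowerChannelConfig()
        c = self.cfg
        self._sos_bp = sps.butter(c.bp_order, [c.band.lo, c.band.hi],
                                  btype="bandpass", fs=c.fs_in, output="sos")
        self._sos_lp = sps.butter(2, c.smooth_hz, btype="lowpass",
                                  fs=c.fs_in, output="sos")
        self._zi_bp = np.zeros((self._sos_bp.shape[0], 2))
        self._zi_lp = np.zeros((self._sos_lp.shape[0], 2))
        self._n_in = 0
        self._k_out = 0

    def process(self, chunk: np.ndarray,
                stim_on: bool = False) -> list[PowerSample]:
        chunk = np.asarray(chunk, dtype=float)
        if chunk.size == 0:
            return []
        y, self._zi_bp = sps.sosfilt(self._sos_bp, chunk, zi=self._zi_bp)
        p, self._zi_lp = sps.sosfilt(self._sos_lp, y * y, zi=self._zi_lp)
        out: list[PowerSample] = []
        c = self.cfg
        step = c.fs_in / c.output_rate
        end = self._n_in + chunk.size
        while True:
            idx = round(self._k_out * step)
            if idx >= end:
                break
            if idx >= self._n_in:
                val = self._quantize(p[idx - self._n_in])
                out.append(PowerSample(t=self._k_out / c.output_rate,
                                       value_lsb=val, band=c.band.label,
                                       stim_on=bool(stim_on)))
            self._k_out += 1
        self._n_in = end
        return out

    def _quantize(self, power: float) -> int:
        v = max(power, 0.0) / self.cfg.lsb_scale
        lsb = int(math.floor(v + 0.5))  # round half away from zero (v >= 0)
        return min(lsb, self.cfg.full_scale)


def band_power(samples: np.ndarray, cfg: PowerChannelConfig | None = None,
               stim_on: np.ndarray | bool = False) -> pd.DataFrame:
    """Run a full record through the power chain; columns t/band/value_lsb/stim_on."""
    cfg = cfg if cfg is not None else PowerChannelConfig()
    x = np.asarray(samples, dtype=float)
    if x.size < cfg.fs_in:
        raise ValueError("need at least 1 s of input")
    chan = StreamingPowerChannel(cfg)
    flags = np.broadcast_to(np.asarray(stim_on, dtype=bool), x.shape)
    # split at stim-flag changes so each emitted sample carries its flag
    change = np.flatnonzero(np.diff(flags.astype(np.int8))) + 1
    rows: list[PowerSample] = []
    start = 0
    for stop in list(change) + [x.size]:
        rows.extend(chan.process(x[start:stop], stim_on=bool(flags[start])))
        start = stop
    return pd.DataFrame([vars(r) for r in rows],
                        columns=["t", "value_lsb", "band", "stim_on"])


def rms_in_band(samples: np.ndarray, band: BandSpec,
                fs: float = 422.0) -> float:
    """Band rms (uVrms) from a Hann-windowed periodogram integrated over the band.

    Analysis-side helper mirroring how state amplitudes are reported; needs at
    least 2 s of input for a usable frequency resolution.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of input")
    f, psd = sps.periodogram(x, fs=fs, window="hann", detrend=False)
    df = f[1] - f[0]
    mask = (f >= band.lo) & (f <= band.hi)
    return float(math.sqrt(np.sum(psd[mask]) * df))
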