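"""Latency-bounded telemetry link and device-side failsafe.

The external ("hybrid") control loop closes through a wireless channel whose
round-trip behavior is modeled as a contract, not a protocol: each direction
delivers messages with stochastic latency (truncated log-normal, median
0.5 s, hard cap 1.0 s), may drop or corrupt messages, and preserves in-order
delivery.  Integrity checking is modeled as a per-message validity flag — a
corrupted payload is delivered flagged invalid and is never acted on.

The device side enforces safety: commands outside the pre-programmed
amplitude interlock are rejected (logged, not raised), and if no valid
command arrives for ``failsafe_timeout`` seconds the device reverts to its
safe pre-programmed stimulation state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .plant import StimInput, STIM_OFF

__all__ = ["LinkConfig", "Message", "TelemetryLink", "DeviceReceiver"]


@dataclass
class LinkConfig:
    latency_typical: float = 0.5  # seconds, median of the latency draw
    latency_max: float = 1.0  # hard cap
    latency_sigma: float = 0.3  # log-normal shape
    drop_prob: float = 0.0
    corrupt_prob: float = 0.0
    failsafe_timeout: float = 5.0  # seconds without a valid command
    safe_command: StimInput = field(default_factory=lambda: STIM_OFF)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.latency_typical <= self.latency_max):
            raise ValueError("require 0 < latency_typical <= latency_max")
        if not (0 <= self.drop_prob < 1 and 0 <= self.corrupt_prob < 1):
            raise ValueError("probabilities must lie in [0, 1)")
        if self.failsafe_timeout <= self.latency_max:
            raise ValueError("failsafe_timeout must exceed latency_max")


@dataclass
class Message:
    payload: Any
    t_sent: float
    t_deliver: float
    valid: bool = True


class TelemetryLink:
    """One direction of the channel: send now, poll for deliveries later."""

    def __init__(self, cfg: LinkConfig | None = None,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None) -> None:
        self.cfg = cfg if cfg is not None else LinkConfig()
        if rng is None:
            rng = np.random.default_rng(
                seed if seed is not None else self.cfg.seed)
        self.rng = rng
        self._queue: list[Message] = []
        self._last_deliver = -math.inf
        self.log: list[dict] = []

    def draw_latency(self) -> float:
        c = self.cfg
        if c.latency_typical == c.latency_max and c.latency_sigma == 0:
            return c.latency_max
        lat = float(self.rng.lognormal(math.log(c.latency_typical),
                                       c.latency_sigma))
        return min(lat, c.latency_max)

    def transmit(self, payload: Any, t_sent: float) -> Message | None:
        """Queue a message; returns it, or None if the channel drops it."""
        c = self.cfg
        if c.drop_prob > 0 and self.rng.random() < c.drop_prob:
            self.log.append({"event": "dropped", "t": t_sent})
            return None
        valid = not (c.corrupt_prob > 0 and self.rng.random() < c.corrupt_prob)
        t_deliver = t_sent + self.draw_latency()
        # in-order delivery within this direction
        if t_deliver < self._last_deliver:
            t_deliver = self._last_deliver
        self._last_deliver = t_deliver
        msg = Message(payload=payload, t_sent=t_sent, t_deliver=t_deliver,
                      valid=valid)
        self._queue.append(msg)
        self.log.append({"event": "sent", "t": t_sent,
                         "t_deliver": t_deliver, "valid": valid})
        return msg

    def poll(self, now: float) -> list[Message]:
        """Messages whose delivery time has arrived, in order."""
        due = [m for m in self._queue if m.t_deliver <= now]
        self._queue = [m for m in self._queue if m.t_deliver > now]
        due.sort(key=lambda m: m.t_deliver)
        for m in due:
            self.log.append({"event": "delivered", "t": m.t_deliver,
                             "valid": m.valid})
        return due


class DeviceReceiver:
    """Device-side command intake with interlock and failsafe."""

    def __init__(self, cfg: LinkConfig | None = None,
                 amp_max: float = 1.7, amp_min: float = 0.0,
                 initial_command: StimInput | None = None) -> None:
        self.cfg = cfg if cfg is not None else LinkConfig()
        self.amp_max = amp_max
        self.amp_min = amp_min
        self.current = (initial_command if initial_command is not None
                        else self.cfg.safe_command)
        self.last_valid_t = 0.0
        self.failsafe_engaged = False
        self.log: list[dict] = []

    def receive(self, msg: Message, now: float) -> StimInput:
        """Apply an arriving command message; returns the command in force."""
        cmd = msg.payload
        if not msg.valid:
            self.log.append({"event": "rejected_crc", "t": now})
            return self.command_in_force(now)
        if not isinstance(cmd, StimInput) or not (
                self.amp_min <= cmd.amplitude <= self.amp_max):
            self.log.append({"event": "rejected_interlock", "t": now,
                             "amplitude": getattr(cmd, "amplitude", None)})
            return self.command_in_force(now)
        self.current = cmd
        self.last_valid_t = now
        if self.failsafe_engaged:
            self.failsafe_engaged = False
            self.log.append({"event": "failsafe_cleared", "t": now})
        return self.command_in_force(now)

    def command_in_force(self, now: float) -> StimInput:
        if (not self.failsafe_engaged
                and now - self.last_valid_t >= self.cfg.failsafe_timeout):
            self.failsafe_engaged = True
            self.log.append({"event": "failsafe", "t": now})
        return self.cfg.safe_command if self.failsafe_engaged else self.current
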