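"""Linear-discriminant event detection on power-channel features.

The external learning tool trains a linear decision boundary over 5 Hz
power-channel feature vectors (by default the 20 +- 2.5 Hz biomarker band and
the ~70 Hz stimulation-energy band, so events remain detectable during
stimulation).  Training uses a ridge-regularized Fisher discriminant:

    w  ∝  (S_w + λ I)^{-1} (m_event − m_nonevent)

with the bias placed at the midpoint of the projected class means.  The
margin ``w·x + b`` is positive on the event side; a margin of exactly zero is
classified as non-event (conservative tie-break).

On-line detection applies *duration constraints*: a detection asserts only
after ``onset_count`` consecutive event-side samples and clears only after
``termination_count`` consecutive non-event samples, trading latency for
specificity.  With the default onset count of one, assertion latency is a
single 5 Hz sample (200 ms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "LabeledSegment",
    "LinearBoundary",
    "DurationConstraints",
    "DetectorPhase",
    "DetectionEvent",
    "train_fisher",
    "margin_histogram",
    "roc",
    "cross_validate",
    "apply_duration_constraints",
    "DurationFilter",
    "StreamingDetector",
    "detect_stream",
    "add_tapped_delays",
]

EVENT = "EVENT"
NON_EVENT = "NON_EVENT"


@dataclass
class LabeledSegment:
    """Annotated 5 Hz feature segment from one recording.

    ``discard_mask`` flags transient samples excluded from training (e.g.
    filter settling at the segment edges).
    """

    features: np.ndarray  # (n_samples, n_features)
    label: str  # EVENT or NON_EVENT
    discard_mask: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.label not in (EVENT, NON_EVENT):
            raise ValueError(f"label must be {EVENT} or {NON_EVENT}")
        if self.discard_mask is None:
            self.discard_mask = np.zeros(len(self.features), dtype=bool)
        else:
            self.discard_mask = np.asarray(self.discard_mask, dtype=bool)
        if len(self.discard_mask) != len(self.features):
            raise ValueError("discard_mask and features must have equal length")
        if not np.any(~self.discard_mask):
            raise ValueError("segment has no usable samples")

    @property
    def usable(self) -> np.ndarray:
        return self.features[~self.discard_mask]


@dataclass
class LinearBoundary:
    """Trained linear discriminant: margin(x) = weights . x + bias."""

    weights: np.ndarray
    bias: float
    feature_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.any(self.weights != 0):
            raise ValueError("boundary needs at least one nonzero weight")

    def margin(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            if x.shape[0] != self.weights.shape[0]:
                raise ValueError("feature dimensionality mismatch")
            return float(x @ self.weights + self.bias)
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError("feature dimensionality mismatch")
        return x @ self.weights + self.bias

    def decide(self, x: np.ndarray) -> np.ndarray:
        """Per-sample decision; margin > 0 is event side (ties -> non-event)."""
        return np.asarray(self.margin(np.atleast_2d(x))) > 0

    def to_json(self) -> str:
        return json.dumps({"weights": self.weights.tolist(),
                           "bias": self.bias,
                           "feature_labels": self.feature_labels})

    @classmethod
    def from_json(cls, text: str) -> "LinearBoundary":
        d = json.loads(text)
        return cls(weights=np.asarray(d["weights"]), bias=float(d["bias"]),
                   feature_labels=list(d.get("feature_labels", [])))


@dataclass
class DurationConstraints:
    onset_count: int = 1  # 1 sample at 5 Hz -> 200 ms assertion latency
    termination_count: int = 5  # 1 s clear hysteresis

    def __post_init__(self) -> None:
        if self.onset_count < 1 or self.termination_count < 1:
            raise ValueError("duration constraints must be >= 1")


class DetectorPhase(str, Enum):
    IDLE = "IDLE"
    PRE_DETECTION = "PRE_DETECTION"
    DETECTED = "DETECTED"


@dataclass
class DetectionEvent:
    onset_t: float
    clear_t: float | None
    peak_margin: float


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _pool(segments) -> np.ndarray:
    segs = [s.usable if isinstance(s, LabeledSegment)
            else np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    if not segs:
        raise ValueError("empty class: need at least one segment")
    return np.vstack(segs)


def train_fisher(event_segments, nonevent_segments,
                 feature_selection: list[int] | None = None,
                 feature_labels: list[str] | None = None,
                 ridge: float = 1e-3) -> LinearBoundary:
    """Fit a regularized Fisher discriminant.

    ``ridge`` scales the identity added to the pooled within-class scatter as
    a fraction of its mean diagonal (trace / dimension), keeping the solve
    well conditioned when a feature is near-constant.
    """
    x1 = _pool(event_segments)
    x0 = _pool(nonevent_segments)
    if feature_selection is not None:
        x1 = x1[:, feature_selection]
        x0 = x0[:, feature_selection]
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x0))):
        raise ValueError("features must be finite")
    m1 = x1.mean(axis=0)
    m0 = x0.mean(axis=0)
    d = x1.shape[1]
    sw = np.zeros((d, d))
    for x, m in ((x1, m1), (x0, m0)):
        c = x - m
        sw += c.T @ c
    lam = ridge * np.trace(sw) / d
    if lam <= 0:
        lam = ridge  # degenerate scatter (identical samples): pure ridge
    sw_reg = sw + lam * np.eye(d)
    try:
        w = np.linalg.solve(sw_reg, m1 - m0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "within-class scatter singular even after regularization") from exc
    if not np.any(w != 0):
        raise ValueError("classes have identical means: no discriminant")
    bias = -float(w @ (m1 + m0)) / 2.0
    boundary = LinearBoundary(weights=w, bias=bias,
                              feature_labels=feature_labels or [])
    # the returned boundary must put both training means on the right side
    if not (boundary.margin(m1) > 0 and boundary.margin(m0) < 0):
        raise ArithmeticError("training means not separated; check inputs")
    return boundary


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------

def margin_histogram(boundary: LinearBoundary, segments,
                     bins: int = 50) -> dict:
    """Histogram of margins by true class over shared bin edges."""
    if not segments:
        raise ValueError("segments must be non-empty")
    margins = {EVENT: [], NON_EVENT: []}
    for s in segments:
        margins[s.label].append(np.atleast_1d(boundary.margin(s.usable)))
    allm = np.concatenate([m for v in margins.values() for m in v])
    edges = np.histogram_bin_edges(allm, bins=bins)
    out = {"edges": edges}
    for label, chunks in margins.items():
        vals = np.concatenate(chunks) if chunks else np.empty(0)
        out[label], _ = np.histogram(vals, bins=edges)
    return out


def roc(boundary: LinearBoundary, segments,
        thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """TP/FP percentages of ``margin > threshold`` over a threshold sweep."""
    ev = np.concatenate([np.atleast_1d(boundary.margin(s.usable))
                         for s in segments if s.label == EVENT])
    ne = np.concatenate([np.atleast_1d(boundary.margin(s.usable))
                         for s in segments if s.label == NON_EVENT])
    if thresholds is None:
        allm = np.concatenate([ev, ne])
        thresholds = np.quantile(allm, np.linspace(0, 1, 101))
        thresholds = np.concatenate(([-np.inf], np.unique(thresholds), [np.inf]))
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    tp = [100.0 * np.mean(ev > th) for th in thresholds]
    fp = [100.0 * np.mean(ne > th) for th in thresholds]
    return pd.DataFrame({"threshold": thresholds, "tp_pct": tp, "fp_pct": fp})


def cross_validate(event_segments, nonevent_segments, k: int = 5,
                   seed: int | None = None, **fit_kw) -> dict:
    """Segment-level k-fold cross-validation (never splits within a segment).

    Returns pooled held-out sensitivity and specificity in percent.
    """
    rng = np.random.default_rng(seed)
    tagged = ([(s, EVENT) for s in event_segments]
              + [(s, NON_EVENT) for s in nonevent_segments])
    order = rng.permutation(len(tagged))
    folds = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(tagged[idx])
    tp = fn = tn = fp = 0
    for i in range(k):
        test = folds[i]
        train = [t for j in range(k) if j != i for t in folds[j]]
        tr_ev = [s for s, lab in train if lab == EVENT]
        tr_ne = [s for s, lab in train if lab == NON_EVENT]
        if not tr_ev or not tr_ne or not test:
            continue
        b = train_fisher(tr_ev, tr_ne, **fit_kw)
        for s, lab in test:
            dec = b.decide(s.usable)
            if lab == EVENT:
                tp += int(dec.sum())
                fn += int((~dec).sum())
            else:
                fp += int(dec.sum())
                tn += int((~dec).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return {"sensitivity_pct": sens, "specificity_pct": spec, "k": k}


# ----------------------------------------------------------------------
# on-line detection with duration constraints
# ----------------------------------------------------------------------

class DurationFilter:
    """Streaming onset/termination constraint logic."""

    def __init__(self, constraints: DurationConstraints) -> None:
        self.c = constraints
        self.phase = DetectorPhase.IDLE
        self.run_length = 0
        self._term_run = 0

    def update(self, decision: bool) -> DetectorPhase:
        c = self.c
        if self.phase is DetectorPhase.DETECTED:
            if decision:
                self._term_run = 0
            else:
                self._term_run += 1
                if self._term_run >= c.termination_count:
                    self.phase = DetectorPhase.IDLE
                    self.run_length = 0
                    self._term_run = 0
        else:
            if decision:
                self.run_length += 1
                if self.run_length >= c.onset_count:
                    self.phase = DetectorPhase.DETECTED
                    self._term_run = 0
                else:
                    self.phase = DetectorPhase.PRE_DETECTION
            else:
                self.run_length = 0
                self.phase = DetectorPhase.IDLE
        return self.phase


def apply_duration_constraints(decisions, constraints: DurationConstraints,
                               rate: float = 5.0, t0: float = 0.0):
    """Filter raw per-sample decisions through the duration constraints.

    Returns (phases, assert_indices): the per-sample phase sequence and the
    indices where a detection first asserts.  Assertion time for index i is
    ``t0 + i / rate``.
    """
    decisions = np.asarray(decisions).astype(bool)
    filt = DurationFilter(constraints)
    phases = []
    asserts = []
    prev = DetectorPhase.IDLE
    for i, d in enumerate(decisions):
        ph = filt.update(bool(d))
        if ph is DetectorPhase.DETECTED and prev is not DetectorPhase.DETECTED:
            asserts.append(i)
        prev = ph
        phases.append(ph)
    return phases, asserts


class StreamingDetector:
    """Boundary + duration constraints applied to a live feature stream."""

    def __init__(self, boundary: LinearBoundary,
                 constraints: DurationConstraints | None = None) -> None:
        self.boundary = boundary
        self.filter = DurationFilter(constraints or DurationConstraints())
        self.events: list[DetectionEvent] = []
        self._open: DetectionEvent | None = None
        self.phase = DetectorPhase.IDLE

    @property
    def detected(self) -> bool:
        return self.phase is DetectorPhase.DETECTED

    def update(self, x: np.ndarray, t: float) -> DetectorPhase:
        m = float(self.boundary.margin(np.asarray(x, dtype=float)))
        prev = self.filter.phase
        ph = self.filter.update(m > 0)
        if ph is DetectorPhase.DETECTED:
            if prev is not DetectorPhase.DETECTED:
                self._open = DetectionEvent(onset_t=t, clear_t=None,
                                            peak_margin=m)
                self.events.append(self._open)
            elif self._open is not None:
                self._open.peak_margin = max(self._open.peak_margin, m)
        elif prev is DetectorPhase.DETECTED and self._open is not None:
            self._open.clear_t = t
            self._open = None
        self.phase = ph
        return ph


def detect_stream(boundary: LinearBoundary, constraints: DurationConstraints,
                  features: np.ndarray, rate: float = 5.0, t0: float = 0.0):
    """Run a whole 5 Hz feature stream through the detector.

    Returns (events, trace) where trace is a DataFrame with per-sample time,
    margin, raw decision and filtered phase — suitable for validation
    overlays.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != boundary.weights.shape[0]:
        raise ValueError("feature dimensionality mismatch")
    det = StreamingDetector(boundary, constraints)
    rows = []
    for i, x in enumerate(features):
        t = t0 + i / rate
        ph = det.update(x, t)
        rows.append((t, float(boundary.margin(x)),
                     bool(boundary.margin(x) > 0), ph.value))
    trace = pd.DataFrame(rows, columns=["t", "margin", "decision", "phase"])
    return det.events, trace


def add_tapped_delays(features: np.ndarray, n_taps: int) -> np.ndarray:
    """Augment a (n, d) feature stream with ``n_taps`` delayed copies."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    cols = [x]
    for k in range(1, n_taps + 1):
        shifted = np.vstack([np.repeat(x[:1], k, axis=0), x[:-k]])
        cols.append(shifted)
    return np.hstack(cols)
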