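"""Activation-time detection, electrode silencing and beat-rate quantification.

The activation time at an electrode is the moment of the steepest negative
voltage slope (dV/dt_min) of its smoothed field-potential trace inside the
user-chosen analysis window.  The numeric gradient uses central differences
in the interior and one-sided differences at the ends (MATLAB ``gradient``
semantics).  Detection has sample resolution: no sub-sample interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mea_io import ElectrodeLayout, MEARecording
from .preprocess import SmoothingConfig, sg_smooth, smooth_recording
from .util import robust_sd

__all__ = [
    "AnalysisWindow",
    "SilenceMask",
    "ActivationMap",
    "DetectionResult",
    "numeric_gradient",
    "detect_activation_time",
    "detect_activation_map",
    "silence_electrodes",
    "unsilence_electrodes",
    "detect_beats",
    "beat_rate",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [start, start+size) in ms (the GUI's two sliders)."""

    start_ms: float
    size_ms: float

    def __post_init__(self) -> None:
        if self.size_ms <= 0:
            raise ValueError("window size must be positive")

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.size_ms

    def sample_indices(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Indices of samples falling inside the window."""
        dt = 1000.0 / sampling_rate
        lo = int(np.ceil(self.start_ms / dt - 1e-9))
        hi = int(np.ceil(self.end_ms / dt - 1e-9))
        lo = max(lo, 0)
        hi = min(hi, n_samples)
        return np.arange(lo, hi)

    def contains(self, t_ms: float) -> bool:
        return self.start_ms <= t_ms < self.end_ms


@dataclass(frozen=True)
class SilenceMask:
    """Electrodes excluded from detection and fitting."""

    silenced: frozenset = field(default_factory=frozenset)

    def __contains__(self, label: str) -> bool:
        return label in self.silenced


def _check_labels(labels, layout: ElectrodeLayout) -> frozenset:
    labs = frozenset(labels)
    unknown = sorted(labs - set(layout.labels))
    if unknown:
        raise KeyError(f"unknown electrode label(s): {', '.join(unknown)}")
    return labs


def silence_electrodes(mask: SilenceMask, labels, layout: ElectrodeLayout) -> SilenceMask:
    """Add electrodes to the mask (idempotent)."""
    return SilenceMask(mask.silenced | _check_labels(labels, layout))


def unsilence_electrodes(mask: SilenceMask, labels, layout: ElectrodeLayout) -> SilenceMask:
    """Remove electrodes from the mask (idempotent)."""
    return SilenceMask(mask.silenced - _check_labels(labels, layout))


@dataclass(frozen=True)
class DetectionResult:
    """One detected activation: its time and the slope there (uV/ms)."""

    time_ms: float
    slope: float

    @property
    def has_downstroke(self) -> bool:
        """False when the steepest gradient is non-negative (no real downstroke)."""
        return self.slope < 0


@dataclass
class ActivationMap:
    """Per-electrode activation times within one analysis window.

    ``times`` and ``min_gradient`` are keyed by electrode label; silenced
    electrodes are absent.  ``min_gradient`` is the trace gradient at the
    detected time, a quality cue for manual silencing (a non-negative value
    means the window contained no downstroke).
    """

    times: dict[str, float]
    min_gradient: dict[str, float]
    window: AnalysisWindow
    mask: SilenceMask = field(default_factory=SilenceMask)

    def __post_init__(self) -> None:
        if set(self.times) != set(self.min_gradient):
            raise ValueError("times and min_gradient must cover the same electrodes")
        bad = [lab for lab in self.times if lab in self.mask]
        if bad:
            raise ValueError(f"silenced electrodes carry times: {bad}")
        for lab, t in self.times.items():
            if not self.window.contains(t):
                raise ValueError(f"time {t} ms of electrode {lab} lies outside the window")

    @property
    def labels(self) -> list[str]:
        return sorted(self.times, key=int)

    def to_json(self, path=None) -> str:
        doc = {
            "window": {"start_ms": self.window.start_ms, "size_ms": self.window.size_ms},
            "silenced": sorted(self.mask.silenced, key=int),
            "electrodes": {
                lab: {"time_ms": self.times[lab], "slope": self.min_gradient[lab]}
                for lab in self.labels
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ActivationMap":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (ValueError, TypeError):
                with open(source, "r", encoding="utf-8") as fh:
                    doc = json.load(fh)
        window = AnalysisWindow(doc["window"]["start_ms"], doc["window"]["size_ms"])
        mask = SilenceMask(frozenset(doc.get("silenced", ())))
        times = {lab: rec["time_ms"] for lab, rec in doc["electrodes"].items()}
        grads = {lab: rec["slope"] for lab, rec in doc["electrodes"].items()}
        return cls(times, grads, window, mask)


def numeric_gradient(values: np.ndarray, dt: float) -> np.ndarray:
    """Numeric derivative: central differences inside, one-sided at the ends."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 values")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(v, dt)


def detect_activation_time(
    trace: np.ndarray,
    window: AnalysisWindow,
    sampling_rate: float,
    smoothing: SmoothingConfig | None = SmoothingConfig(),
    presmoothed: bool = False,
) -> DetectionResult:
    """Steepest-negative-gradient activation time of one trace.

    The gradient of the smoothed trace is evaluated over the whole trace and
    minimised over the window samples; ties go to the earliest sample.  Pass
    ``smoothing=None`` (or ``presmoothed=True``) to detect on the raw trace.
    """
    y = np.asarray(trace, dtype=float)
    dt = 1000.0 / sampling_rate
    idx = window.sample_indices(y.size, sampling_rate)
    if idx.size == 0:
        raise ValueError("analysis window does not intersect the recording")
    if idx.size < 3:
        raise ValueError("analysis window must contain at least 3 samples")
    if smoothing is not None and smoothing.enabled and not presmoothed:
        y = sg_smooth(y, smoothing)
    grad = numeric_gradient(y, dt)
    k = idx[int(np.argmin(grad[idx]))]  # argmin returns the first minimum
    return DetectionResult(time_ms=k * dt, slope=float(grad[k]))


def detect_activation_map(
    recording: MEARecording,
    window: AnalysisWindow,
    mask: SilenceMask | None = None,
    smoothing: SmoothingConfig | None = SmoothingConfig(),
    presmoothed: bool = False,
) -> ActivationMap:
    """Apply :func:`detect_activation_time` to every non-silenced electrode.

    The same window is applied to all electrodes; silenced electrodes are
    skipped entirely.
    """
    mask = mask or SilenceMask()
    _check_labels(mask.silenced, recording.layout)
    active = [lab for lab in recording.layout.labels if lab not in mask]
    if not active:
        raise ValueError("all electrodes are silenced")
    rec = recording
    if smoothing is not None and smoothing.enabled and not presmoothed:
        rec = smooth_recording(recording, smoothing)
    times: dict[str, float] = {}
    grads: dict[str, float] = {}
    for lab in active:
        res = detect_activation_time(
            rec.trace(lab), window, rec.sampling_rate, smoothing=None
        )
        times[lab] = res.time_ms
        grads[lab] = res.slope
    return ActivationMap(times, grads, window, mask)


def detect_beats(
    trace: np.ndarray,
    sampling_rate: float,
    threshold_k: float = 5.0,
    refractory_ms: float = 100.0,
    smoothing: SmoothingConfig | None = SmoothingConfig(),
) -> np.ndarray:
    """Beat (field-potential downstroke) times in ms for one electrode.

    An event is declared where the smoothed-trace gradient falls below
    ``-threshold_k`` robust standard deviations of the gradient series; only
    the steepest sample per refractory period is kept, so returned times are
    sorted with pairwise gaps >= ``refractory_ms``.  The threshold is
    relative, making detection invariant to trace scaling.
    """
    if refractory_ms <= 0:
        raise ValueError("refractory_ms must be positive")
    y = np.asarray(trace, dtype=float)
    if smoothing is not None and smoothing.enabled and y.size >= smoothing.frame:
        y = sg_smooth(y, smoothing)
    dt = 1000.0 / sampling_rate
    grad = numeric_gradient(y, dt)
    scale = robust_sd(grad)
    if scale == 0:
        return np.empty(0)
    thr = -threshold_k * scale
    cand = np.flatnonzero(grad < thr)
    if cand.size == 0:
        return np.empty(0)
    # greedy: steepest first, suppress neighbours within the refractory period
    order = cand[np.argsort(grad[cand], kind="stable")]
    refr = refractory_ms / dt
    accepted: list[int] = []
    for k in order:
        if all(abs(k - a) >= refr for a in accepted):
            accepted.append(k)
    return np.sort(np.array(accepted)) * dt


def beat_rate(event_times, duration_ms: float) -> float:
    """Beats per minute from detected event times over a recording duration."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    return len(event_times) * 60000.0 / duration_ms
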