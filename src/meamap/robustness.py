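"""Scripted robustness experiments: electrode dropout and added white noise.

Two stress tests of the conduction-velocity pipeline, run as seeded,
reproducible procedures:

* dropout — silence increasing numbers of randomly chosen electrodes, refit
  the activation surface each time, and express the resulting mean
  conduction velocity as a percent of the best estimate (the one using all
  available electrodes);
* white noise — add Gaussian noise of increasing magnitude to the raw
  traces, rerun smoothing/detection/fitting, and record absolute errors in
  activation times and mean conduction velocity against the clean result.

Noise levels are multiples of each trace's robust standard deviation
(median absolute deviation x 1.4826), a scale-free definition that keeps
"level 4" meaningful across recordings of different gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import ActivationMap, AnalysisWindow, SilenceMask, detect_activation_map
from .mea_io import ElectrodeLayout, MEARecording
from .preprocess import SmoothingConfig
from .util import robust_sd
from .velocity import fit_activation_surface, velocity_vectors

__all__ = [
    "DropoutCurve",
    "NoiseCurve",
    "dropout_curve",
    "add_white_noise",
    "noise_curve",
    "jitter_activation_times",
]


@dataclass
class DropoutCurve:
    """Mean-CV estimates under random electrode silencing.

    ``estimates[i, r]`` is the mean conduction velocity (mm/s) of replicate
    ``r`` with ``n_silenced[i]`` electrodes removed; ``percent`` is
    100 x estimate / best_estimate.
    """

    n_silenced: tuple[int, ...]
    estimates: np.ndarray  # shape (len(n_silenced), reps)
    best_estimate: float
    seed: int
    reps: int

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.estimates / self.best_estimate

    def percent_sd(self) -> np.ndarray:
        """Across-replicate SD of percent-of-best, per n."""
        return np.std(self.percent, axis=1)


def dropout_curve(
    activation_map: ActivationMap,
    layout: ElectrodeLayout,
    n_list,
    reps: int = 100,
    seed: int = 0,
) -> DropoutCurve:
    """Randomly silence n electrodes, refit, and compare to the best estimate.

    Electrodes are sampled without replacement within a replicate and
    independently across replicates.  Every subset must leave at least 6
    electrodes for the surface fit.
    """
    n_list = tuple(int(n) for n in n_list)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    available = list(activation_map.labels)
    if max(n_list) > len(available) - 6:
        raise ValueError(
            f"silencing {max(n_list)} of {len(available)} electrodes leaves fewer than 6"
        )
    best_fit = fit_activation_surface(activation_map, layout)
    best = velocity_vectors(best_fit, layout, activation_map.mask).mean_speed
    rng = np.random.default_rng(seed)
    est = np.empty((len(n_list), reps))
    for i, n in enumerate(n_list):
        for r in range(reps):
            drop = rng.choice(available, size=n, replace=False) if n else ()
            fit = fit_activation_surface(activation_map, layout, exclude=drop)
            est[i, r] = velocity_vectors(fit, layout, activation_map.mask).mean_speed
    return DropoutCurve(n_list, est, best, seed, reps)


def jitter_activation_times(
    activation_map: ActivationMap, sd_ms: float, seed: int = 0
) -> ActivationMap:
    """Add seeded Gaussian jitter (SD in ms) to every activation time.

    Jittered times are clipped to the analysis window so the map invariants
    hold; used to emulate detection error in the dropout experiment.
    """
    rng = np.random.default_rng(seed)
    w = activation_map.window
    eps = 1e-9 * max(1.0, abs(w.end_ms))
    times = {
        lab: float(np.clip(t + rng.normal(0.0, sd_ms), w.start_ms, w.end_ms - eps))
        for lab, t in activation_map.times.items()
    }
    return ActivationMap(times, dict(activation_map.min_gradient), w, activation_map.mask)


def add_white_noise(recording: MEARecording, level: float, seed: int = 0) -> MEARecording:
    """Add i.i.d. Gaussian noise, SD = level x robust SD of each clean trace.

    Level 0 returns a recording with identical samples.  The same seed always
    produces the same noise realisation.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return MEARecording(recording.samples.copy(), recording.sampling_rate, recording.layout)
    rng = np.random.default_rng(seed)
    noisy = recording.samples.copy()
    for j in range(noisy.shape[1]):
        sd = level * robust_sd(recording.samples[:, j])
        noisy[:, j] += rng.normal(0.0, 1.0, noisy.shape[0]) * sd
    return MEARecording(noisy, recording.sampling_rate, recording.layout)


@dataclass
class NoiseCurve:
    """Absolute activation-time and mean-CV errors versus noise level.

    ``time_err[i, r]`` is replicate r's mean |activation-time change| (ms)
    over electrodes at ``levels[i]``; ``cv_err`` the |mean-CV change| (mm/s),
    both relative to the zero-noise analysis of the same recording.
    """

    levels: tuple[float, ...]
    time_err: np.ndarray  # (len(levels), reps), ms
    cv_err: np.ndarray  # (len(levels), reps), mm/s
    seed: int
    reps: int

    def summary(self) -> dict:
        """Per-level mean and SEM (SD/sqrt(reps)) of both error metrics."""
        root = np.sqrt(self.reps)
        return {
            "levels": list(self.levels),
            "time_err_mean_ms": np.mean(self.time_err, axis=1).tolist(),
            "time_err_sem_ms": (np.std(self.time_err, axis=1) / root).tolist(),
            "cv_err_mean": np.mean(self.cv_err, axis=1).tolist(),
            "cv_err_sem": (np.std(self.cv_err, axis=1) / root).tolist(),
        }


def noise_curve(
    recording: MEARecording,
    levels,
    window: AnalysisWindow,
    reps: int = 5,
    seed: int = 0,
    smoothing: SmoothingConfig = SmoothingConfig(),
    mask: SilenceMask | None = None,
) -> NoiseCurve:
    """Rerun the full analysis under added white noise at each level.

    For every (level, replicate): add seeded noise to the raw recording,
    re-smooth, re-detect activation times, refit the surface and record the
    mean absolute activation-time change and the absolute mean-CV change
    against the clean analysis.  Level 0 reruns the identical computation and
    therefore yields exactly zero errors.
    """
    levels = tuple(float(l) for l in levels)
    mask = mask or SilenceMask()

    def analyse(rec: MEARecording):
        amap = detect_activation_map(rec, window, mask, smoothing)
        fit = fit_activation_surface(amap, rec.layout)
        cv = velocity_vectors(fit, rec.layout, mask).mean_speed
        return amap, cv

    clean_map, clean_cv = analyse(recording)
    labels = clean_map.labels
    clean_t = np.array([clean_map.times[lab] for lab in labels])
    rng = np.random.default_rng(seed)
    time_err = np.empty((len(levels), reps))
    cv_err = np.empty((len(levels), reps))
    for i, level in enumerate(levels):
        for r in range(reps):
            sub = int(rng.integers(0, 2**31 - 1))
            amap, cv = analyse(add_white_noise(recording, level, sub))
            t = np.array([amap.times[lab] for lab in labels])
            time_err[i, r] = float(np.mean(np.abs(t - clean_t)))
            cv_err[i, r] = abs(cv - clean_cv)
    return NoiseCurve(levels, time_err, cv_err, seed, reps)
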