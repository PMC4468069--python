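"""Savitzky-Golay smoothing of electrode traces and its cutoff predictor.

Field potentials are smoothed once, at load time, with a least-squares
polynomial (Savitzky-Golay) filter; activation detection then runs on the
smoothed traces.  Defaults are polynomial order N = 3 and half-width
M = 50 samples (frame 2M+1 = 101), i.e. 5.05 ms at 20 kHz.

The filter's normalised cutoff frequency f_c = w_c / pi is predicted by

    f_c = (N + 1) / (3.2 M - 4.6)

For the default configuration this evaluates to 4/155.4 ~= 0.02574.  (A
published application of this formula quotes 0.0346 for the same N and M;
that number is not reproducible from the formula and is not used here.)
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import savgol_coeffs

__all__ = [
    "SmoothingConfig",
    "sg_coefficients",
    "sg_smooth",
    "smooth_recording",
    "predicted_cutoff",
    "cutoff_hz",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay parameters: polynomial order and half-width in samples."""

    order: int = 3
    half_width: int = 50
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.frame <= self.order:
            raise ValueError(
                f"frame size {self.frame} must exceed polynomial order {self.order}"
            )

    @property
    def frame(self) -> int:
        """Frame (window) length 2M + 1 in samples."""
        return 2 * self.half_width + 1


def sg_coefficients(config: SmoothingConfig) -> np.ndarray:
    """Mid-point convolution weights of the least-squares polynomial smoother.

    Weights are symmetric and sum to 1 (the filter preserves constants).
    """
    return savgol_coeffs(config.frame, config.order)


@lru_cache(maxsize=32)
def _edge_weights(order: int, half_width: int) -> list[np.ndarray]:
    """Weights for the left-edge positions j = 0..M-1.

    At edge position j the full frame is unavailable; the order-N polynomial
    is least-squares fitted to the truncated window [0, j+M] and evaluated at
    j.  Weight vector w_j satisfies smoothed[j] = w_j . trace[0 : j+M+1].
    """
    weights = []
    for j in range(half_width):
        x = np.arange(j + half_width + 1, dtype=float) - j  # centered at j
        X = np.vander(x, order + 1, increasing=True)
        # value at x=0 is the constant coefficient of the LS fit
        weights.append(np.linalg.pinv(X)[0])
    return weights


def sg_smooth(trace: np.ndarray, config: SmoothingConfig = SmoothingConfig()) -> np.ndarray:
    """Smooth one trace; output has the same length as the input.

    Interior points are the convolution with :func:`sg_coefficients`; the M
    points at each end are fitted with the order-N polynomial on the largest
    available truncated window, which preserves exact reproduction of
    polynomials up to order N at every sample.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("trace must be 1-D")
    return _smooth_columns(y[:, None], config)[:, 0]


def _smooth_columns(samples: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    n = samples.shape[0]
    m = config.half_width
    if n < config.frame:
        raise ValueError(f"trace length {n} is shorter than the frame {config.frame}")
    coeffs = sg_coefficients(config)
    out = np.empty_like(samples, dtype=float)
    # full-frame convolution for the interior
    from scipy.ndimage import convolve1d

    out[:] = convolve1d(samples, coeffs, axis=0, mode="nearest")
    ew = _edge_weights(config.order, config.half_width)
    for j in range(m):
        w = ew[j]
        out[j] = w @ samples[: j + m + 1]
        out[n - 1 - j] = w[::-1] @ samples[n - 1 - j - m :]
    return out


def smooth_recording(recording, config: SmoothingConfig = SmoothingConfig()):
    """Return a new recording with every electrode trace smoothed."""
    from .mea_io import MEARecording

    if not config.enabled:
        return recording
    return MEARecording(
        _smooth_columns(recording.samples, config),
        recording.sampling_rate,
        recording.layout,
    )


def predicted_cutoff(config: SmoothingConfig) -> float:
    """Normalised cutoff frequency f_c = (N+1) / (3.2 M - 4.6), dimensionless."""
    denom = 3.2 * config.half_width - 4.6
    if denom <= 0:
        raise ValueError("3.2*half_width - 4.6 must be positive")
    return (config.order + 1) / denom


def cutoff_hz(
    config: SmoothingConfig,
    sampling_rate: float,
    convention: str = "nyquist",
) -> float:
    """Cutoff in Hz.

    ``convention='nyquist'`` (default) reads f_c as a fraction of the Nyquist
    frequency (f_c = w_c/pi), giving f_c * fs/2; ``convention='fs'``
    multiplies by the sampling rate instead, reproducing the kHz arithmetic
    some applications of this formula use.
    """
    fc = predicted_cutoff(config)
    if convention == "nyquist":
        return fc * sampling_rate / 2.0
    if convention == "fs":
        return fc * sampling_rate
    raise ValueError("convention must be 'nyquist' or 'fs'")
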