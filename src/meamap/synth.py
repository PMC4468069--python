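"""Synthetic MEA recordings with analytically known ground truth.

Stands in for cultured-cardiomyocyte recordings: a biphasic field-potential
template sweeps across the 60-electrode grid as a planar wave, a focal
(point-source, isotropic) wave, or a wave whose arrival times follow a
quadratic surface directly.  Every generated recording carries exact
per-electrode arrival times and closed-form velocity vectors, so detection
and the Bayly fit can be scored against truth.

The default template is

    g(tau) = -A * (tau/w) * exp((1 - (tau/w)^2) / 2)

a biphasic deflection (positive lobe then a dominant negative-going stroke)
whose derivative g'(tau) = -(A/w) * exp((1-(tau/w)^2)/2) * (1 - (tau/w)^2)
has its unique minimum at tau = 0: the steepest-descent point — the event a
dV/dt_min detector marks — coincides analytically with the arrival time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mea_io import ElectrodeLayout, MEARecording, standard_layout
from .util import robust_sd

__all__ = [
    "FPTemplate",
    "WaveSpec",
    "GroundTruth",
    "arrival_time",
    "generate_recording",
    "ground_truth_velocity",
]


@dataclass(frozen=True)
class FPTemplate:
    """Biphasic field-potential waveform g(tau), tau in ms.

    ``amplitude`` is the magnitude of the extrema (uV, reached at
    tau = -w and +w); ``width`` w sets the time scale (ms).  The steepest
    descent is at tau = 0 with slope -amplitude*sqrt(e)/width.
    """

    amplitude: float = 500.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("amplitude and width must be positive")

    #: offset of the steepest-descent point from the template origin (ms)
    steepest_descent_offset: float = 0.0

    @property
    def min_slope(self) -> float:
        """Slope at the steepest-descent point, uV/ms."""
        return -self.amplitude * math.sqrt(math.e) / self.width

    @property
    def support_ms(self) -> float:
        """Half-width beyond which the waveform is negligible (< 1e-7 A)."""
        return 6.0 * self.width

    def __call__(self, tau):
        s = np.asarray(tau, dtype=float) / self.width
        return -self.amplitude * s * np.exp((1.0 - s * s) / 2.0)


@dataclass(frozen=True)
class WaveSpec:
    """Ground-truth description of one propagating wavefront.

    kind 'planar': arrival t0 + (x cos(theta) + y sin(theta)) / speed;
    kind 'focal': arrival t0 + |r - origin| / speed (isotropic point source);
    kind 'quadratic': arrival is the quadratic surface with the given
    coefficients (a..f), the surface the Bayly fit estimates.
    Speeds in mm/s (= um/ms); ``noise_level`` is in multiples of each clean
    trace's robust SD.
    """

    kind: str
    speed: float | None = None
    direction_deg: float | None = None
    origin: tuple[float, float] | None = None
    coefficients: tuple[float, float, float, float, float, float] | None = None
    t0: float = 5.0
    template: FPTemplate = field(default_factory=FPTemplate)
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "focal", "quadratic"):
            raise ValueError(f"unknown wave kind {self.kind!r}")
        if self.kind in ("planar", "focal"):
            if self.speed is None or self.speed <= 0:
                raise ValueError("planar/focal waves need speed > 0")
        if self.kind == "planar" and self.direction_deg is None:
            raise ValueError("planar wave needs a direction")
        if self.kind == "focal" and self.origin is None:
            raise ValueError("focal wave needs an origin")
        if self.kind == "quadratic" and self.coefficients is None:
            raise ValueError("quadratic wave needs coefficients (a..f)")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @classmethod
    def planar(
        cls,
        speed: float,
        direction_deg: float,
        layout: ElectrodeLayout | None = None,
        margin_ms: float | None = None,
        **kw,
    ) -> "WaveSpec":
        """Planar wave with t0 chosen so the earliest arrival is clear of t=0."""
        spec = cls(kind="planar", speed=speed, direction_deg=direction_deg, **kw)
        if margin_ms is None:
            margin_ms = spec.template.support_ms
        layout = layout or standard_layout()
        xy = layout.coords()
        th = math.radians(direction_deg)
        proj = (xy[:, 0] * math.cos(th) + xy[:, 1] * math.sin(th)) / speed
        return replace(spec, t0=margin_ms - float(np.min(proj)))

    @classmethod
    def focal(cls, speed: float, origin: tuple[float, float], **kw) -> "WaveSpec":
        kw.setdefault("t0", 5.0)
        return cls(kind="focal", speed=speed, origin=origin, **kw)

    @classmethod
    def quadratic(cls, coefficients, **kw) -> "WaveSpec":
        return cls(kind="quadratic", coefficients=tuple(coefficients), **kw)


def arrival_time(spec: WaveSpec, x, y):
    """Ground-truth arrival time (ms) at position(s) (x, y) in um."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.kind == "planar":
        th = math.radians(spec.direction_deg)
        return spec.t0 + (x * math.cos(th) + y * math.sin(th)) / spec.speed
    if spec.kind == "focal":
        ox, oy = spec.origin
        return spec.t0 + np.hypot(x - ox, y - oy) / spec.speed
    a, b, c, d, e, f = spec.coefficients
    return spec.t0 + a * x * x + b * y * y + c * x * y + d * x + e * y + f


def ground_truth_velocity(spec: WaveSpec, positions) -> np.ndarray:
    """Closed-form velocity vectors (mm/s) at an (n, 2) array of positions.

    planar: the constant speed*(cos, sin); focal: speed times the unit radial
    vector from the origin (undefined AT the origin); quadratic: the Bayly
    relation V = grad(T) / |grad T|^2 evaluated on the true surface.
    """
    xy = np.atleast_2d(np.asarray(positions, dtype=float))
    if spec.kind == "planar":
        th = math.radians(spec.direction_deg)
        v = spec.speed * np.array([math.cos(th), math.sin(th)])
        return np.tile(v, (xy.shape[0], 1))
    if spec.kind == "focal":
        r = xy - np.asarray(spec.origin, dtype=float)
        dist = np.hypot(r[:, 0], r[:, 1])
        if np.any(dist == 0):
            raise ValueError("focal velocity is undefined at the wave origin")
        return spec.speed * r / dist[:, None]
    a, b, c, d, e, _ = spec.coefficients
    tx = 2 * a * xy[:, 0] + c * xy[:, 1] + d
    ty = 2 * b * xy[:, 1] + c * xy[:, 0] + e
    g2 = tx * tx + ty * ty
    if np.any(g2 == 0):
        raise ValueError("quadratic truth has a stationary point at an electrode")
    return np.column_stack([tx / g2, ty / g2])


@dataclass
class GroundTruth:
    """Exact per-electrode arrival times and velocity vectors of a simulation."""

    times: dict[str, float]  # first-beat arrival per electrode, ms
    vectors: dict[str, tuple[float, float]]  # mm/s
    beat_times: tuple[float, ...]  # offsets added to every arrival, ms
    spec: WaveSpec

    @property
    def mean_speed(self) -> float:
        return float(np.mean([math.hypot(*v) for v in self.vectors.values()]))

    def to_json(self, path=None) -> str:
        doc = {
            "kind": self.spec.kind,
            "beat_times_ms": list(self.beat_times),
            "mean_speed_mm_per_s": self.mean_speed,
            "electrodes": {
                lab: {"time_ms": self.times[lab], "vx": self.vectors[lab][0],
                      "vy": self.vectors[lab][1]}
                for lab in sorted(self.times, key=int)
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def generate_recording(
    spec: WaveSpec,
    layout: ElectrodeLayout | None = None,
    sampling_rate: float = 20000.0,
    duration_ms: float | None = None,
    beat_times: tuple[float, ...] = (0.0,),
) -> tuple[MEARecording, GroundTruth]:
    """Synthesize a recording: template at each electrode's arrival + noise.

    Each electrode's trace is the sum over ``beat_times`` of the template
    shifted to arrival + beat offset, plus (for ``spec.noise_level > 0``)
    seeded i.i.d. Gaussian noise scaled to the clean trace's robust SD.
    ``duration_ms`` defaults to the smallest duration containing every
    waveform; an explicit duration that clips a waveform is an error.
    """
    layout = layout or standard_layout()
    xy = layout.coords()
    arrivals = arrival_time(spec, xy[:, 0], xy[:, 1])
    sup = spec.template.support_ms
    first = float(np.min(arrivals)) + min(beat_times) - sup
    last = float(np.max(arrivals)) + max(beat_times) + sup
    if first < -1e-9:  # tolerance for t0 computed as margin - min(projection)
        raise ValueError(
            f"template extends before t=0 (earliest onset {first:.3f} ms); increase t0"
        )
    if duration_ms is None:
        duration_ms = last + 1000.0 / sampling_rate
    elif duration_ms < last:
        raise ValueError(
            f"duration {duration_ms} ms clips the waveform (needs >= {last:.3f} ms)"
        )
    n = int(round(duration_ms * sampling_rate / 1000.0))
    t = np.arange(n) * (1000.0 / sampling_rate)
    clean = np.zeros((n, len(layout)))
    for j, arr in enumerate(arrivals):
        for b in beat_times:
            clean[:, j] += spec.template(t - arr - b)
    samples = clean
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        noise = np.empty_like(clean)
        for j in range(clean.shape[1]):
            noise[:, j] = rng.normal(0.0, 1.0, n) * (spec.noise_level * robust_sd(clean[:, j]))
        samples = clean + noise
    rec = MEARecording(samples, sampling_rate, layout)
    vecs = ground_truth_velocity(spec, xy)
    truth = GroundTruth(
        times={lab: float(a) for lab, a in zip(layout.labels, arrivals)},
        vectors={lab: (float(v[0]), float(v[1])) for lab, v in zip(layout.labels, vecs)},
        beat_times=tuple(beat_times),
        spec=spec,
    )
    return rec, truth
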