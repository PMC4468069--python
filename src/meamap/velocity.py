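"""Quadratic activation-surface fitting and conduction-velocity vectors.

The activation surface (Bayly method) models per-electrode activation times
t_i at positions (x_i, y_i) as the quadratic polynomial

    T(x, y) = a x^2 + b y^2 + c x y + d x + e y + f

fitted by ordinary least squares over every available electrode.  The local
velocity vector at an electrode is derived from the surface gradient
(T_x, T_y) = (dT/dx, dT/dy) as

    V = (T_x, T_y) / (T_x^2 + T_y^2)

which satisfies V . grad(T) = 1 and |V| = 1 / |grad T|.  With positions in
um and times in ms the gradient is in ms/um and |V| in um/ms, numerically
equal to mm/s — the unit all speeds are reported in.

Raw um^2 design columns reach ~1e6 and would make the normal equations
ill-conditioned, so coordinates are centered and scaled to unit RMS before
solving; the coefficients are transformed back to um/ms units afterwards.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .activation import ActivationMap, SilenceMask
from .mea_io import ElectrodeLayout

__all__ = [
    "SurfaceFit",
    "VelocityField",
    "fit_activation_surface",
    "fit_surface_to_points",
    "predict_time",
    "surface_gradient",
    "velocity_vectors",
    "mean_conduction_velocity",
    "residual_diagnostics",
    "ResidualDiagnostics",
]

#: gradient magnitudes below this (ms/um) are treated as a stationary surface
GRADIENT_TOL = 1e-12


@dataclass(frozen=True)
class SurfaceFit:
    """Least-squares fit of the quadratic activation surface.

    ``coefficients`` are (a, b, c, d, e, f) in um/ms units; ``residuals``
    (observed minus predicted, ms) are keyed by electrode label; ``scaling``
    records the centering/RMS-scaling transform used to condition the solve.
    """

    coefficients: tuple[float, float, float, float, float, float]
    labels: tuple[str, ...]
    residuals: dict[str, float]
    rss: float
    scaling: tuple[float, float, float, float]  # (mx, my, sx, sy)

    @property
    def n_points(self) -> int:
        return len(self.labels)


def _design(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([u * u, v * v, u * v, u, v, np.ones_like(u)])


def fit_surface_to_points(
    x: np.ndarray, y: np.ndarray, t: np.ndarray, labels=None
) -> SurfaceFit:
    """Fit T(x,y) to raw (x, y, t) triples; positions um, times ms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    n = x.size
    if n < 6:
        raise ValueError(f"need at least 6 electrodes to fit the surface, got {n}")
    if labels is None:
        labels = tuple(str(i) for i in range(n))

    mx, my = float(np.mean(x)), float(np.mean(y))
    sx = float(np.sqrt(np.mean((x - mx) ** 2))) or 1.0
    sy = float(np.sqrt(np.mean((y - my) ** 2))) or 1.0
    u, v = (x - mx) / sx, (y - my) / sy

    X = _design(u, v)
    beta, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    if rank < 6:
        warnings.warn(
            "rank-deficient design (electrodes on a degenerate conic); "
            "returning the minimum-norm least-squares surface",
            stacklevel=2,
        )
    A, B, C, D, E, F = beta
    # expand T(u, v) back to raw coordinates
    a = A / sx**2
    b = B / sy**2
    c = C / (sx * sy)
    d = -2 * A * mx / sx**2 - C * my / (sx * sy) + D / sx
    e = -2 * B * my / sy**2 - C * mx / (sx * sy) + E / sy
    f = (
        A * mx**2 / sx**2
        + B * my**2 / sy**2
        + C * mx * my / (sx * sy)
        - D * mx / sx
        - E * my / sy
        + F
    )
    pred = X @ beta
    res = t - pred
    return SurfaceFit(
        coefficients=(float(a), float(b), float(c), float(d), float(e), float(f)),
        labels=tuple(labels),
        residuals={lab: float(r) for lab, r in zip(labels, res)},
        rss=float(np.dot(res, res)),
        scaling=(mx, my, sx, sy),
    )


def fit_activation_surface(
    activation_map: ActivationMap,
    layout: ElectrodeLayout,
    exclude=(),
) -> SurfaceFit:
    """Fit the surface to all detected, non-silenced activation times.

    ``exclude`` silences additional electrodes for this fit only (used by the
    dropout experiment).
    """
    drop = set(exclude) | set(activation_map.mask.silenced)
    labels = tuple(lab for lab in activation_map.labels if lab not in drop)
    if len(labels) < 6:
        raise ValueError(
            f"fewer than 6 electrodes available for the surface fit ({len(labels)})"
        )
    xy = layout.coords(labels)
    t = np.array([activation_map.times[lab] for lab in labels])
    return fit_surface_to_points(xy[:, 0], xy[:, 1], t, labels)


def predict_time(fit: SurfaceFit, x, y):
    """Surface value T(x, y) in ms (vectorised)."""
    a, b, c, d, e, f = fit.coefficients
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return a * x * x + b * y * y + c * x * y + d * x + e * y + f


def surface_gradient(fit: SurfaceFit, x, y):
    """Surface gradient (T_x, T_y) in ms/um: (2ax + cy + d, 2by + cx + e)."""
    a, b, c, d, e, _ = fit.coefficients
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 2 * a * x + c * y + d, 2 * b * y + c * x + e


@dataclass
class VelocityField:
    """Per-electrode velocity vectors derived from a surface fit.

    All per-label dicts cover the defined electrodes only; ``undefined``
    lists electrodes whose surface gradient magnitude fell below the
    stationarity tolerance (no meaningful propagation direction there).
    Speeds and vector components are in mm/s, directions in degrees
    (atan2 convention, 0 = +x, counter-clockwise).
    """

    vx: dict[str, float]
    vy: dict[str, float]
    speed: dict[str, float]
    direction_deg: dict[str, float]
    tx: dict[str, float]
    ty: dict[str, float]
    undefined: frozenset
    fit: SurfaceFit | None = None

    @property
    def labels(self) -> list[str]:
        return sorted(self.speed, key=int)

    @property
    def mean_speed(self) -> float:
        """Mean local conduction velocity (mm/s) over defined electrodes."""
        return float(np.mean([self.speed[lab] for lab in self.labels]))

    def to_json(self, path=None) -> str:
        doc = {
            "coefficients": dict(zip("abcdef", self.fit.coefficients)) if self.fit else None,
            "mean_speed_mm_per_s": self.mean_speed,
            "undefined": sorted(self.undefined, key=int),
            "electrodes": {
                lab: {
                    "vx": self.vx[lab],
                    "vy": self.vy[lab],
                    "speed": self.speed[lab],
                    "direction_deg": self.direction_deg[lab],
                }
                for lab in self.labels
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def velocity_vectors(
    fit: SurfaceFit,
    layout: ElectrodeLayout,
    mask: SilenceMask | None = None,
    tol: float = GRADIENT_TOL,
) -> VelocityField:
    """Evaluate V = (T_x, T_y)/(T_x^2 + T_y^2) at every non-silenced electrode.

    Electrodes where |grad T| < ``tol`` ms/um are reported as undefined and
    excluded from the mean speed; if all are undefined the surface is
    stationary and an error is raised.
    """
    mask = mask or SilenceMask()
    labels = [lab for lab in layout.labels if lab not in mask]
    xy = layout.coords(tuple(labels))
    tx, ty = surface_gradient(fit, xy[:, 0], xy[:, 1])
    g2 = tx * tx + ty * ty
    defined = np.sqrt(g2) >= tol
    if not np.any(defined):
        raise ValueError("stationary activation surface: velocity undefined everywhere")
    field = VelocityField({}, {}, {}, {}, {}, {}, undefined=frozenset(), fit=fit)
    undef = set()
    for i, lab in enumerate(labels):
        if not defined[i]:
            undef.add(lab)
            continue
        vx = tx[i] / g2[i]  # um/ms == mm/s
        vy = ty[i] / g2[i]
        field.vx[lab] = float(vx)
        field.vy[lab] = float(vy)
        field.speed[lab] = float(1.0 / math.sqrt(g2[i]))
        field.direction_deg[lab] = float(math.degrees(math.atan2(vy, vx)))
        field.tx[lab] = float(tx[i])
        field.ty[lab] = float(ty[i])
    field.undefined = frozenset(undef)
    return field


def mean_conduction_velocity(field: VelocityField) -> float:
    """Arithmetic mean of per-electrode speeds (mm/s)."""
    if not field.speed:
        raise ValueError("no defined velocity vectors")
    return field.mean_speed


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Goodness-of-fit summary for an activation-surface fit.

    A good fit has residuals approximately normally distributed around zero
    and unstructured against the predicted activation times.  ``shapiro_w``
    and ``shapiro_p`` are the Shapiro-Wilk normality statistic and p-value
    (NaN when the residuals are numerically constant, e.g. an exact fit).
    """

    mean: float
    sd: float
    pairs: tuple[tuple[str, float, float], ...]  # (label, predicted, residual)
    shapiro_w: float
    shapiro_p: float


def residual_diagnostics(fit: SurfaceFit, layout: ElectrodeLayout) -> ResidualDiagnostics:
    """Residual mean/SD, predicted-vs-residual pairs and a normality check."""
    labels = fit.labels
    xy = layout.coords(labels)
    pred = predict_time(fit, xy[:, 0], xy[:, 1])
    res = np.array([fit.residuals[lab] for lab in labels])
    pairs = tuple((lab, float(p), float(r)) for lab, p, r in zip(labels, pred, res))
    if res.size >= 3 and np.ptp(res) > 1e-12 * max(1.0, float(np.max(np.abs(res)))):
        w, p = stats.shapiro(res)
    else:
        w, p = float("nan"), float("nan")
    return ResidualDiagnostics(
        mean=float(np.mean(res)),
        sd=float(np.sqrt(np.mean(res**2))),
        pairs=pairs,
        shapiro_w=float(w),
        shapiro_p=float(p),
    )
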