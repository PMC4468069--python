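"""Electrode geometry and ASCII I/O for multielectrode-array recordings.

The standard array is the 8x8-minus-corners 60-electrode grid (TiN planar
electrodes, 200 um pitch) used by Multi Channel Systems hardware.  Electrode
labels follow the MCS two-digit convention: first digit = column (1-8),
second digit = row (1-8); the four corner positions 11, 18, 81 and 88 carry
no electrode.

Coordinate convention: label CR sits at x = (C-1)*pitch, y = (R-1)*pitch,
with row 1 at the BOTTOM, so y increases upward and electrode 12 is one
pitch above the origin.  Units are micrometres for positions, milliseconds
for time and microvolts for voltage throughout the package.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MEAFormatError",
    "MEADataError",
    "ElectrodeLayout",
    "MEARecording",
    "DialectConfig",
    "standard_layout",
    "read_ascii_recording",
    "write_ascii_recording",
]

DEFAULT_PITCH_UM = 200.0
_CORNERS = frozenset({"11", "18", "81", "88"})


class MEAFormatError(ValueError):
    """Raised when a file does not conform to the ASCII recording dialect."""


class MEADataError(ValueError):
    """Raised when a file parses but its numeric content is inconsistent."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode labels and their planar coordinates.

    Parameters
    ----------
    labels
        Electrode labels, in the column order used by sample matrices.
    positions
        Mapping label -> (x, y) in micrometres.
    pitch
        Nominal inter-electrode distance in micrometres.
    """

    labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    pitch: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        if set(self.labels) != set(self.positions):
            raise ValueError("labels and positions disagree")
        coords = list(self.positions.values())
        if len(set(coords)) != len(coords):
            raise ValueError("electrode positions must be distinct")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    def coords(self, labels: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
        """Positions as an (n, 2) array in um, in ``labels`` order."""
        use = self.labels if labels is None else labels
        return np.array([self.positions[lab] for lab in use], dtype=float)

    def replace_positions(self, positions: dict[str, tuple[float, float]]) -> "ElectrodeLayout":
        """New layout with the same labels but transformed coordinates."""
        return ElectrodeLayout(self.labels, dict(positions), self.pitch)


def standard_layout(pitch: float = DEFAULT_PITCH_UM) -> ElectrodeLayout:
    """The 8x8-minus-corners 60-electrode grid at the given pitch (um).

    Label CR maps to x = (C-1)*pitch, y = (R-1)*pitch with row 1 at the
    bottom (y up).  Labels are returned in ascending numeric order
    (12, 13, ..., 87), the order MC_DataTool exports columns in.
    """
    labels = []
    positions = {}
    for col in range(1, 9):
        for row in range(1, 9):
            lab = f"{col}{row}"
            if lab in _CORNERS:
                continue
            labels.append(lab)
            positions[lab] = ((col - 1) * pitch, (row - 1) * pitch)
    labels.sort(key=int)
    return ElectrodeLayout(tuple(labels), positions, pitch)


@dataclass
class MEARecording:
    """A voltage sample matrix plus its sampling rate and electrode layout.

    ``samples`` has one row per time point and one column per electrode, in
    ``layout.labels`` order, in microvolts.  Time is implicit: sample ``i``
    is at ``i / sampling_rate`` seconds (``times_ms`` gives milliseconds).
    """

    samples: np.ndarray
    sampling_rate: float
    layout: ElectrodeLayout

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D matrix (time x electrodes)")
        if self.samples.shape[1] != len(self.layout):
            raise ValueError(
                f"sample matrix has {self.samples.shape[1]} columns but the "
                f"layout defines {len(self.layout)} electrodes"
            )
        if self.samples.shape[0] < 2:
            raise ValueError("a recording needs at least 2 time points")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise MEADataError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def dt_ms(self) -> float:
        """Sample interval in milliseconds."""
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def trace(self, label: str) -> np.ndarray:
        """The voltage trace (uV) of one electrode."""
        return self.samples[:, self.layout.index(label)]


@dataclass(frozen=True)
class DialectConfig:
    """Overrides for the ASCII dialect auto-detection.

    ``delimiter`` is one of '\\t', ';', ',' or None (auto).  ``time_unit``
    forces 'ms' or 'us' interpretation of the time column when the header
    carries no unit tag.
    """

    delimiter: str | None = None
    time_unit: str | None = None


_LABEL_RE = re.compile(r"^(?:El\s*)?(\d{2})\s*(?:\[[^\]]*\])?$")
_TIME_RE = re.compile(r"^t\s*(?:\[(\w+)\])?$", re.IGNORECASE)


def _detect_delimiter(header: str) -> str:
    for cand in ("\t", ";", ","):
        if cand in header:
            return cand
    raise MEAFormatError("could not detect a delimiter (tab/;/,) in the header line")


def _parse_header(header: str, delimiter: str) -> tuple[str, list[str]]:
    """Return (time_unit, electrode labels in file column order)."""
    fields = [f.strip() for f in header.split(delimiter)]
    if len(fields) < 2:
        raise MEAFormatError("header has fewer than 2 columns")
    m = _TIME_RE.match(fields[0])
    if not m:
        raise MEAFormatError(f"first header column {fields[0]!r} is not a time column")
    unit = (m.group(1) or "ms").lower().replace("µ", "u")
    if unit not in ("ms", "us"):
        raise MEAFormatError(f"unsupported time unit {unit!r} (expected ms or us)")
    labels = []
    for col, f in enumerate(fields[1:], start=2):
        lm = _LABEL_RE.match(f.replace("µ", "u"))
        if not lm:
            raise MEAFormatError(f"header column {col} ({f!r}) is not an electrode label")
        labels.append(lm.group(1))
    return unit, labels


def read_ascii_recording(
    path,
    dialect: DialectConfig | None = None,
    layout: ElectrodeLayout | None = None,
) -> MEARecording:
    """Read an MC_DataTool-style ASCII export.

    Line 1 (after optional ``#`` comment lines) is a header naming the time
    column (``t [ms]`` or ``t [us]``) and one electrode column per label
    (``El 12 [uV]`` or bare ``12``); subsequent lines are delimiter-separated
    decimal numbers, one time point per line.  The sampling rate is inferred
    from the median of successive time differences; jitter beyond 1 ppm is
    rejected (resampling is out of scope).
    """
    dialect = dialect or DialectConfig()
    layout = layout or standard_layout()
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if len(body) < 3:
        raise MEAFormatError("file needs a header line and at least 2 data rows")
    delimiter = dialect.delimiter or _detect_delimiter(body[0])
    unit, file_labels = _parse_header(body[0], delimiter)
    if dialect.time_unit is not None:
        unit = dialect.time_unit

    want = set(layout.labels)
    seen: set[str] = set()
    for lab in file_labels:
        if lab in seen:
            raise MEAFormatError(f"duplicate electrode column {lab!r}")
        seen.add(lab)
    missing = sorted(want - seen, key=int)
    if missing:
        raise MEAFormatError(f"missing electrode column(s): {', '.join(missing)}")
    extra = sorted(seen - want, key=int)
    if extra:
        raise MEAFormatError(f"unknown electrode column(s): {', '.join(extra)}")

    n_cols = len(file_labels) + 1
    data = np.empty((len(body) - 1, n_cols), dtype=float)
    for i, ln in enumerate(body[1:], start=2):
        cells = ln.split(delimiter)
        if len(cells) != n_cols:
            raise MEAFormatError(f"line {i}: expected {n_cols} columns, got {len(cells)}")
        for j, cell in enumerate(cells):
            try:
                data[i - 2, j] = float(cell)
            except ValueError:
                raise MEADataError(
                    f"line {i}, column {j + 1}: unparsable numeric cell {cell.strip()!r}"
                ) from None

    t = data[:, 0]
    if unit == "us":
        t = t / 1000.0
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise MEADataError("time column is not strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 * dt:
        raise MEADataError("time column jitter exceeds 1 ppm; not a uniform sampling grid")
    sampling_rate = 1000.0 / dt

    # reorder file columns into layout label order
    order = [file_labels.index(lab) + 1 for lab in layout.labels]
    return MEARecording(data[:, order], sampling_rate, layout)


def write_ascii_recording(
    recording: MEARecording,
    path,
    precision: int = 6,
    delimiter: str = "\t",
) -> None:
    """Write the default ASCII dialect (tab-delimited, ``El NN [uV]`` header).

    Voltages are written with ``precision`` significant digits; the time
    column always gets 10 significant digits so the sampling grid survives
    the round trip.
    """
    if precision < 1:
        raise ValueError("precision must be >= 1")
    layout = recording.layout
    header = delimiter.join(["t [ms]"] + [f"El {lab} [µV]" for lab in layout.labels])
    t = recording.times_ms
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for i in range(recording.n_samples):
            row = [f"{t[i]:.10g}"]
            row.extend(f"{v:.{precision}g}" for v in recording.samples[i])
            fh.write(delimiter.join(row) + "\n")


def roundtrip_tolerance(values: np.ndarray, precision: int) -> np.ndarray:
    """Worst-case absolute formatting error for %.{precision}g rendering."""
    v = np.abs(np.asarray(values, dtype=float))
    exp = np.where(v > 0, np.ceil(np.log10(np.maximum(v, 1e-300))), -precision)
    return 0.5 * 10.0 ** (exp - precision + 1)
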