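"""Figure rendering: trace grids, activation heat maps, isochrone maps,
velocity vector fields and 3-D signal-progression frames.

Every function writes a figure file and returns a :class:`PlotResult`
carrying the path plus the numbers that went into the plot (times, vectors,
contour levels, per-frame metadata), so tests and downstream scripts can
assert on data rather than pixels.  Axis labels state the coordinate
convention (x rightward, y upward, row 1 at the bottom).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .activation import ActivationMap, AnalysisWindow
from .mea_io import ElectrodeLayout, MEARecording
from .velocity import SurfaceFit, VelocityField, fit_activation_surface, predict_time

__all__ = [
    "FigureSpec",
    "PlotResult",
    "trace_grid",
    "activation_heatmap",
    "isoline_map",
    "vector_field_plot",
    "render_3d_frames",
]


@dataclass(frozen=True)
class FigureSpec:
    """Shared figure options."""

    colormap: str = "jet"  # earliest activation = blue end
    isolines: int = 10
    annotate: bool = True
    stride: int = 1
    dpi: int = 110

    def __post_init__(self) -> None:
        if self.isolines < 2:
            raise ValueError("need at least 2 isolines")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class PlotResult:
    """A written figure plus the structured data it renders."""

    path: str
    data: dict = field(default_factory=dict)


def _grid_rc(layout: ElectrodeLayout, label: str) -> tuple[int, int]:
    """(row, col) cell of a label on an 8x8 display grid, row 8 at the top."""
    col, row = int(label[0]), int(label[1])
    return 8 - row, col - 1


def _times_grid(amap: ActivationMap, layout: ElectrodeLayout) -> np.ndarray:
    grid = np.full((8, 8), np.nan)
    for lab, t in amap.times.items():
        r, c = _grid_rc(layout, lab)
        grid[r, c] = t
    return grid


def trace_grid(
    recording: MEARecording,
    window: AnalysisWindow | None = None,
    selected_label: str | None = None,
    activation_map: ActivationMap | None = None,
    path: str = "traces.png",
    spec: FigureSpec = FigureSpec(),
) -> PlotResult:
    """8x8 grid of voltage traces (corners blank), or a single electrode.

    In single-electrode mode the detected activation time (if an activation
    map is supplied) is marked with a green dot on the trace.
    """
    t = recording.times_ms
    if window is not None:
        idx = window.sample_indices(recording.n_samples, recording.sampling_rate)
    else:
        idx = np.arange(recording.n_samples)
    marked_time = None
    if selected_label is not None:
        trace = recording.trace(selected_label)  # raises KeyError if unknown
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(t[idx], trace[idx], lw=0.8)
        if activation_map is not None and selected_label in activation_map.times:
            marked_time = activation_map.times[selected_label]
            k = int(round(marked_time / recording.dt_ms))
            ax.plot([marked_time], [trace[k]], "go", ms=8, label="activation time")
            ax.legend(loc="best", fontsize=8)
        ax.set_xlabel("time [ms]")
        ax.set_ylabel(f"El {selected_label} [µV]")
        n_panels = 1
    else:
        fig, axes = plt.subplots(8, 8, figsize=(12, 10), sharex=True, sharey=True)
        for ax in axes.ravel():
            ax.axis("off")
        for lab in recording.layout.labels:
            r, c = _grid_rc(recording.layout, lab)
            ax = axes[r, c]
            ax.axis("on")
            ax.plot(t[idx], recording.trace(lab)[idx], lw=0.5)
            ax.set_xticks([])
            ax.set_yticks([])
            ax.set_title(lab, fontsize=6, pad=1)
        fig.suptitle("voltage traces (x rightward, y up; row 1 bottom)", fontsize=9)
        n_panels = len(recording.layout)
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    return PlotResult(str(path), {"n_panels": n_panels, "marked_time_ms": marked_time,
                                  "n_samples_shown": int(idx.size)})


def activation_heatmap(
    amap: ActivationMap,
    layout: ElectrodeLayout,
    annotate: bool = True,
    path: str = "heatmap.png",
    spec: FigureSpec = FigureSpec(),
) -> PlotResult:
    """Color-coded 8x8 grid of activation times with numeric annotations.

    Silenced or missing electrodes (and the four corners) render as blank
    grey cells without numbers.  Earliest times map to the low (blue) end of
    the colormap.
    """
    if not amap.times:
        raise ValueError("activation map is empty")
    grid = _times_grid(amap, layout)
    cmap = plt.get_cmap(spec.colormap).copy()
    cmap.set_bad("0.85")
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(grid, cmap=cmap, origin="upper")
    if annotate:
        for lab, t in amap.times.items():
            r, c = _grid_rc(layout, lab)
            ax.text(c, r, f"{t:.2f}", ha="center", va="center", fontsize=7)
    ax.set_xticks(range(8), [str(c) for c in range(1, 9)])
    ax.set_yticks(range(8), [str(r) for r in range(8, 0, -1)])
    ax.set_xlabel("column (x rightward)")
    ax.set_ylabel("row (y upward, row 1 bottom)")
    fig.colorbar(im, ax=ax, label="activation time [ms]")
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    vmin, vmax = float(np.nanmin(grid)), float(np.nanmax(grid))
    return PlotResult(str(path), {"grid": grid, "vmin": vmin, "vmax": vmax,
                                  "n_annotated": len(amap.times) if annotate else 0})


def isoline_map(
    amap: ActivationMap,
    layout: ElectrodeLayout,
    n_levels: int | None = None,
    path: str = "isolines.png",
    spec: FigureSpec = FigureSpec(),
    fit: SurfaceFit | None = None,
) -> PlotResult:
    """Isochrone (equal-activation-time) contour map over the array.

    Missing/silenced cells are imputed from the fitted activation surface
    before contouring, so the isolines use the same model the velocity
    analysis trusts.  Widely spaced isolines mean fast conduction.
    """
    n_levels = n_levels or spec.isolines
    if len(amap.times) < 6:
        raise ValueError("need at least 6 activation times to draw isolines")
    if fit is None:
        fit = fit_activation_surface(amap, layout)
    grid = _times_grid(amap, layout)
    pitch = layout.pitch
    for r in range(8):
        for c in range(8):
            if np.isnan(grid[r, c]):
                x, y = c * pitch, (7 - r) * pitch
                grid[r, c] = float(predict_time(fit, x, y))
    xs = np.arange(8) * pitch
    ys = np.arange(8) * pitch
    fig, ax = plt.subplots(figsize=(7, 6))
    field = grid[::-1]  # row index 0 -> y=0 for contouring
    pm = ax.pcolormesh(xs, ys, field, cmap=spec.colormap, shading="gouraud")
    cs = ax.contour(xs, ys, field, levels=n_levels, colors="k", linewidths=0.8)
    ax.clabel(cs, fontsize=6, fmt="%.2f")
    ax.set_xlabel("x [µm] (rightward)")
    ax.set_ylabel("y [µm] (upward; row 1 bottom)")
    ax.set_aspect("equal")
    fig.colorbar(pm, ax=ax, label="activation time [ms]")
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    return PlotResult(str(path), {"levels": np.asarray(cs.levels).tolist(),
                                  "grid": field, "n_imputed": int(np.isnan(_times_grid(amap, layout)).sum())})


def vector_field_plot(
    field: VelocityField,
    layout: ElectrodeLayout,
    path: str = "vectors.png",
    spec: FigureSpec = FigureSpec(),
) -> PlotResult:
    """Quiver plot of velocity vectors; annotates the mean conduction velocity.

    Undefined electrodes (stationary surface gradient) are drawn as open
    markers, not arrows.
    """
    if not field.speed:
        raise ValueError("no defined velocity vectors to plot")
    labels = field.labels
    xy = layout.coords(tuple(labels))
    vx = np.array([field.vx[lab] for lab in labels])
    vy = np.array([field.vy[lab] for lab in labels])
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.quiver(xy[:, 0], xy[:, 1], vx, vy, np.hypot(vx, vy),
              cmap=spec.colormap, angles="xy")
    if field.undefined:
        uxy = layout.coords(tuple(sorted(field.undefined, key=int)))
        ax.plot(uxy[:, 0], uxy[:, 1], "o", mfc="none", mec="k", ms=6)
    ax.set_xlabel("x [µm] (rightward)")
    ax.set_ylabel("y [µm] (upward; row 1 bottom)")
    ax.set_aspect("equal")
    ax.set_title(f"mean local conduction velocity = {field.mean_speed:.1f} mm/s")
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    angles = {lab: float(np.degrees(np.arctan2(field.vy[lab], field.vx[lab])))
              for lab in labels}
    return PlotResult(str(path), {"angles_deg": angles, "mean_speed": field.mean_speed,
                                  "n_arrows": len(labels),
                                  "n_undefined": len(field.undefined)})


def render_3d_frames(
    recording: MEARecording,
    window: AnalysisWindow,
    stride: int = 20,
    out: str = "frames",
    spec: FigureSpec = FigureSpec(),
) -> PlotResult:
    """3-D voltage-surface frames of the RAW signal over the 8x8 grid.

    One frame per ``stride`` samples inside the window, with a z-axis fixed
    across frames.  ``out`` ending in ``.gif`` assembles an animated GIF
    (25 fps); otherwise ``out`` is a directory of numbered PNG frames.
    At the default 20 kHz and stride 20 a ~9 ms event becomes ~1 s of video,
    about 100x slower than real time.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = window.sample_indices(recording.n_samples, recording.sampling_rate)
    if idx.size == 0:
        raise ValueError("window contains no samples")
    frames_idx = idx[::stride]
    pitch = recording.layout.pitch
    zmin = float(np.min(recording.samples[idx]))
    zmax = float(np.max(recording.samples[idx]))
    if zmin == zmax:
        zmin, zmax = zmin - 1.0, zmax + 1.0
    X, Y = np.meshgrid(np.arange(8) * pitch, np.arange(8) * pitch)

    as_gif = str(out).endswith(".gif")
    if not as_gif:
        os.makedirs(out, exist_ok=True)
    images = []
    frame_paths = []
    argmax_labels = []
    max_values = []
    for fno, k in enumerate(frames_idx):
        grid = np.full((8, 8), 0.0)
        best_lab, best_v = None, -np.inf
        for lab in recording.layout.labels:
            col, row = int(lab[0]) - 1, int(lab[1]) - 1
            v = recording.samples[k, recording.layout.index(lab)]
            grid[row, col] = v
            if v > best_v:
                best_lab, best_v = lab, v
        argmax_labels.append(best_lab)
        max_values.append(float(best_v))
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        ax.plot_surface(X, Y, grid, cmap=spec.colormap, vmin=zmin, vmax=zmax)
        ax.set_zlim(zmin, zmax)
        ax.set_xlabel("x [µm]")
        ax.set_ylabel("y [µm]")
        ax.set_zlabel("raw voltage [µV]")
        ax.set_title(f"t = {k * recording.dt_ms:.3f} ms")
        if as_gif:
            fig.canvas.draw()
            images.append(np.asarray(fig.canvas.buffer_rgba())[..., :3].copy())
        else:
            fp = os.path.join(out, f"frame_{fno:04d}.png")
            fig.savefig(fp, dpi=spec.dpi)
            frame_paths.append(fp)
        plt.close(fig)
    if as_gif:
        import imageio.v3 as iio

        iio.imwrite(out, np.stack(images), duration=40, loop=0)  # 25 fps
    return PlotResult(str(out), {
        "n_frames": len(frames_idx),
        "frame_times_ms": (frames_idx * recording.dt_ms).tolist(),
        "argmax_label_per_frame": argmax_labels,
        "max_voltage_per_frame": max_values,
        "frame_paths": frame_paths,
        "zlim": (zmin, zmax),
    })
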