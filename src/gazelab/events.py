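"""Kinematic analysis of gaze recordings.

Velocity and acceleration come from a two-point differentiator (forward
differences assigned to interval midpoints); no smoothing is applied by
default, matching the visibly noisy raw derivative traces such low-rate
trackers produce.  Saccades are detected by velocity threshold with
onset/offset refinement to a fraction of the event peak; fixations by the
dispersion-window (I-DT) algorithm; vergence is the left-minus-right
horizontal gaze angle (convergence positive); pursuit gain is median eye
velocity over a closed-loop window divided by target velocity; fixation maps
are Gaussian-kernel-smoothed 2D histograms normalized to unit mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, angular_distance
from .io import GazeRecording

__all__ = [
    "differentiate",
    "moving_average",
    "Saccade",
    "detect_saccades",
    "saccade_latency",
    "Fixation",
    "detect_fixations",
    "inter_fixation_saccade_metrics",
    "vergence_trace",
    "pursuit_gain",
    "FixationMap",
    "fixation_map",
]


def differentiate(x, t) -> tuple[np.ndarray, np.ndarray]:
    """Two-point (forward-difference) derivative at interval midpoints.

    ``x`` may be (n,) or (n, m); ``t`` is in ms and strictly increasing.
    Returns ``(dx_dt, t_mid)`` with the derivative in units of x per second.
    Applied twice this yields acceleration on a further-shortened time base.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("differentiate requires at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    d = np.diff(x, axis=0)
    v = (d.T / (dt / 1000.0)).T
    return v, (t[:-1] + t[1:]) / 2.0


def moving_average(x, width: int) -> np.ndarray:
    """Centered moving average (optional pre-smoothing; off by default)."""
    if width <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width) / width
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="same")
    return np.column_stack([np.convolve(x[:, j], kernel, mode="same") for j in range(x.shape[1])])


@dataclass(frozen=True)
class Saccade:
    """A detected saccade with its kinematic metrics."""

    onset_ms: float
    offset_ms: float
    duration_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    peak_accel_deg_s2: float
    peak_decel_deg_s2: float
    latency_from_target_ms: float | None = None


def detect_saccades(
    positions,
    timestamps,
    v_threshold: float = 30.0,
    onset_fraction: float = 0.1,
    min_duration_ms: float = 10.0,
) -> list[Saccade]:
    """Velocity-threshold saccade detector with peak-fraction refinement.

    Contiguous runs of speed above ``v_threshold`` seed events; onset and
    offset are walked outward to where speed falls below ``onset_fraction``
    of the event peak, then extended by one sample so the boundary intervals
    (which contain the partial displacement a forward differentiator spreads
    across them) are counted.  Amplitude is the straight-line position change
    from onset to offset; events shorter than ``min_duration_ms`` are
    discarded.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    t = np.asarray(timestamps, dtype=float)
    v, t_mid = differentiate(pos, t)
    speed = np.linalg.norm(v, axis=1)
    above = speed > v_threshold
    events: list[tuple[int, int]] = []
    i = 0
    n = len(speed)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        peak = speed[i : j + 1].max()
        lo = onset_fraction * peak
        i0, i1 = i, j
        while i0 > 0 and speed[i0 - 1] >= lo:
            i0 -= 1
        while i1 + 1 < n and speed[i1 + 1] >= lo:
            i1 += 1
        i0 = max(i0 - 1, 0)
        i1 = min(i1 + 1, n - 1)
        if events and i0 <= events[-1][1]:
            events[-1] = (events[-1][0], i1)  # merge overlapping refinements
        else:
            events.append((i0, i1))
        i = i1 + 1
    out = []
    for i0, i1 in events:
        onset, offset = float(t_mid[i0]), float(t_mid[i1])
        if offset - onset < min_duration_ms:
            continue
        amp = float(np.linalg.norm(pos[i1 + 1] - pos[i0]))
        seg_speed = speed[i0 : i1 + 1]
        if i1 > i0:
            acc = np.diff(seg_speed) / (np.diff(t_mid[i0 : i1 + 1]) / 1000.0)
            pk_acc, pk_dec = float(acc.max()), float(acc.min())
        else:
            pk_acc = pk_dec = 0.0
        out.append(
            Saccade(
                onset_ms=onset,
                offset_ms=offset,
                duration_ms=offset - onset,
                amplitude_deg=amp,
                peak_velocity_deg_s=float(seg_speed.max()),
                peak_accel_deg_s2=pk_acc,
                peak_decel_deg_s2=pk_dec,
            )
        )
    return out


def saccade_latency(events, target_onset_ms: float, target_step_deg: float) -> float | None:
    """Latency of the first response saccade to a target step.

    The response is the first event at or after target onset whose amplitude
    is at least half the target step; earlier (anticipatory) saccades are
    ignored.  Returns None when no event qualifies.
    """
    for ev in events:
        if ev.onset_ms >= target_onset_ms and ev.amplitude_deg >= target_step_deg / 2.0:
            return ev.onset_ms - target_onset_ms
    return None


@dataclass(frozen=True)
class Fixation:
    start_ms: float
    end_ms: float
    duration_ms: float
    centroid: tuple[float, float]
    dispersion_deg: float
    n_samples: int


def _dispersion(xy: np.ndarray) -> float:
    return float((xy[:, 0].max() - xy[:, 0].min()) + (xy[:, 1].max() - xy[:, 1].min()))


def detect_fixations(
    rec: GazeRecording,
    eye: str = "left",
    dispersion_threshold_deg: float = 1.0,
    min_duration_ms: float = 100.0,
) -> list[Fixation]:
    """Dispersion-window (I-DT) fixation detector.

    A window covering at least ``min_duration_ms`` is accepted as a fixation
    when (max-min in x) + (max-min in y) stays within the threshold, then
    grown while it remains so.  Centroids are component medians.
    """
    t, xy = rec.eye_positions(eye, valid_only=True)
    n = len(t)
    out: list[Fixation] = []
    i = 0
    while i < n:
        j = int(np.searchsorted(t, t[i] + min_duration_ms))
        if j >= n:
            break
        if _dispersion(xy[i : j + 1]) > dispersion_threshold_deg:
            i += 1
            continue
        while j + 1 < n and _dispersion(xy[i : j + 2]) <= dispersion_threshold_deg:
            j += 1
        seg = xy[i : j + 1]
        out.append(
            Fixation(
                start_ms=float(t[i]),
                end_ms=float(t[j]),
                duration_ms=float(t[j] - t[i]),
                centroid=(float(np.median(seg[:, 0])), float(np.median(seg[:, 1]))),
                dispersion_deg=_dispersion(seg),
                n_samples=j - i + 1,
            )
        )
        i = j + 1
    return out


def inter_fixation_saccade_metrics(
    fixations,
    positions=None,
    timestamps=None,
    geom: ScreenGeometry | None = None,
) -> pd.DataFrame:
    """Amplitude and peak velocity of the saccades between consecutive fixations.

    Amplitude is the distance between consecutive centroids (true angular
    distance when a geometry is given, Euclidean in degree coordinates
    otherwise).  Peak velocity is read from the two-point velocity trace in
    the inter-fixation gap when positions/timestamps are supplied.
    """
    fixations = list(fixations)
    if len(fixations) < 2:
        return pd.DataFrame(columns=["amplitude_deg", "peak_velocity_deg_s"])
    speed = t_mid = None
    if positions is not None and timestamps is not None:
        v, t_mid = differentiate(np.asarray(positions, float), np.asarray(timestamps, float))
        speed = np.abs(v) if v.ndim == 1 else np.linalg.norm(v, axis=1)
    rows = []
    for a, b in zip(fixations[:-1], fixations[1:]):
        if geom is not None:
            amp = angular_distance(a.centroid, b.centroid, geom)
        else:
            amp = math.hypot(b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1])
        pk = np.nan
        if speed is not None:
            gap = (t_mid > a.end_ms) & (t_mid < b.start_ms)
            if gap.any():
                pk = float(speed[gap].max())
        rows.append({"amplitude_deg": float(amp), "peak_velocity_deg_s": pk})
    return pd.DataFrame(rows)


def vergence_trace(
    rec: GazeRecording,
    baseline_window_ms: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal vergence angle over time (convergence positive).

    vergence(t) = left_x(t) - right_x(t) over samples valid in both eyes.
    With a baseline window the trace is re-zeroed to its median there, so
    zero corresponds to fixation in the screen plane.
    """
    cond = rec.meta.get("condition", "binocular")
    if cond != "binocular":
        raise ValueError(f"vergence requires a binocular recording, got condition {cond!r}")
    df = rec.samples
    both = (df["left_valid"] == 1) & (df["right_valid"] == 1)
    t = df.loc[both, "t_ms"].to_numpy(dtype=float)
    verg = (df.loc[both, "left_x_deg"] - df.loc[both, "right_x_deg"]).to_numpy(dtype=float)
    if baseline_window_ms is not None:
        w0, w1 = baseline_window_ms
        sel = (t >= w0) & (t <= w1)
        if sel.any():
            verg = verg - np.median(verg[sel])
    return t, verg


def pursuit_gain(
    timestamps,
    positions,
    target_velocity_deg_s: float,
    window_ms: tuple[float, float],
) -> float:
    """Closed-loop pursuit gain: median eye velocity / target velocity.

    ``positions`` is the 1D gaze coordinate along the pursuit axis; the
    window (in the trace's time base) should cover the closed-loop tracking
    phase, after the initial catch-up.
    """
    if target_velocity_deg_s == 0:
        raise ValueError("target velocity must be nonzero")
    v, t_mid = differentiate(np.asarray(positions, float), np.asarray(timestamps, float))
    w0, w1 = window_ms
    sel = (t_mid >= w0) & (t_mid <= w1)
    if not sel.any():
        raise ValueError("closed-loop window contains no velocity samples")
    return float(np.median(v[sel]) / target_velocity_deg_s)


@dataclass(frozen=True)
class FixationMap:
    """Smoothed 2D gaze density over the workspace, integrating to one."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    density: np.ndarray          # (ny, nx), density per deg^2
    bandwidth_deg: float
    extent_deg: tuple[float, float, float, float]

    @property
    def cell_area_deg2(self) -> float:
        dx = self.x_centers[1] - self.x_centers[0] if len(self.x_centers) > 1 else 1.0
        dy = self.y_centers[1] - self.y_centers[0] if len(self.y_centers) > 1 else 1.0
        return float(dx * dy)

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area_deg2)

    def contour_levels(self, quantiles=(0.5, 0.75, 0.9)) -> list[float]:
        return [float(np.quantile(self.density, q)) for q in quantiles]

    def to_dict(self) -> dict:
        return {
            "x_centers": self.x_centers.tolist(),
            "y_centers": self.y_centers.tolist(),
            "density": self.density.tolist(),
            "bandwidth_deg": self.bandwidth_deg,
            "extent_deg": list(self.extent_deg),
        }


def _silverman(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0


def fixation_map(
    points,
    grid: tuple[int, int] = (96, 54),
    extent_deg: tuple[float, float, float, float] = (-18.0, 18.0, -10.5, 10.5),
    bandwidth_deg: float | str = "auto",
) -> FixationMap:
    """Kernel-density fixation map on a regular grid.

    Gaussian kernel; "auto" bandwidth is Silverman's rule per axis, averaged
    (falling back to one grid cell for degenerate inputs).  The returned
    density times cell area sums to exactly one.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("fixation_map requires at least one point")
    nx, ny = grid
    x0, x1, y0, y1 = extent_deg
    xc = np.linspace(x0, x1, nx)
    yc = np.linspace(y0, y1, ny)
    if bandwidth_deg == "auto":
        h = 0.5 * (_silverman(pts[:, 0]) + _silverman(pts[:, 1]))
        if h <= 0:
            h = max((x1 - x0) / nx, (y1 - y0) / ny)
    else:
        h = float(bandwidth_deg)
        if h <= 0:
            raise ValueError("bandwidth_deg must be positive")
    gx, gy = np.meshgrid(xc, yc)
    dens = np.zeros_like(gx)
    inv = 1.0 / (2.0 * h * h)
    for chunk in np.array_split(pts, max(1, len(pts) // 2048 + 1)):
        dx = gx[..., None] - chunk[:, 0]
        dy = gy[..., None] - chunk[:, 1]
        dens += np.exp(-(dx * dx + dy * dy) * inv).sum(axis=-1)
    cell = (xc[1] - xc[0]) * (yc[1] - yc[0]) if nx > 1 and ny > 1 else 1.0
    total = dens.sum() * cell
    if total <= 0:
        raise ValueError("all points fall outside the map extent")
    return FixationMap(
        x_centers=xc, y_centers=yc, density=dens / total,
        bandwidth_deg=h, extent_deg=tuple(extent_deg),
    )
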