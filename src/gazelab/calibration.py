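"""Gaze calibration: target layouts, median aggregation, retry rule, and
biharmonic error-surface correction.

The procedure: fixation targets are shown in random order for ~2 s each; the
first 0.5 s of each dwell (often contaminated by compensatory saccades) is
discarded and the gaze position taken as the component-wise median of the
remaining valid samples.  The per-target error vectors (median gaze minus
target) are then interpolated over the screen with a biharmonic radial basis
surface, separately per axis and per eye; the fitted surface is subtracted
from each raw measurement to correct it, online or offline.  Targets whose
error exceeds 0.5 deg are flagged for re-measurement.

The surface uses the 2D biharmonic Green's function g(r) = r^2 (ln r - 1)
(g(0) = 0) with a constant (mean) term per axis, giving exact scattered-data
interpolation of the target errors; an optional ridge parameter trades
exactness for smoothing on noisy data.  Outside the convex hull of the
calibration targets the surface extrapolates, and evaluations are flagged.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.base import BaseEstimator

from .geometry import DegPoint, ScreenGeometry, working_range
from .io import GazeRecording

__all__ = [
    "CalibrationLayout",
    "make_layout",
    "TargetObservation",
    "aggregate_target",
    "flag_retries",
    "BiharmonicSurface",
    "fit_surface",
    "evaluate_surface",
    "GazeCalibrator",
    "apply_correction",
    "run_test",
    "InsufficientDataError",
]

LAYOUT_NAMES = ("5P", "9P", "13P", "TEST12")


class InsufficientDataError(ValueError):
    """Raised when too few valid samples remain to aggregate."""


@dataclass(frozen=True)
class CalibrationLayout:
    """Named, ordered set of on-screen calibration/test targets (deg)."""

    name: str
    targets: tuple[DegPoint, ...]

    def __len__(self) -> int:
        return len(self.targets)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.targets, dtype=float)


def make_layout(name: str, geom: ScreenGeometry, margin_frac: float = 0.1) -> CalibrationLayout:
    """Construct a standard layout scaled to the screen's angular workspace.

    5P: screen center + four corners; 9P adds the four cross arms (edge
    midpoints); 13P adds four mid-quadrant diagonal points at half the corner
    offsets, for finer coverage.  The point sets nest: 5P ⊂ 9P ⊂ 13P.
    TEST12 is a 4x3 grid interleaved between the calibration points, used to
    evaluate a calibration on targets it was not fitted on.  Outermost points
    sit at ``(1 - margin_frac)`` of the workspace half-ranges.
    """
    if name not in LAYOUT_NAMES:
        raise KeyError(f"unknown layout {name!r}; expected one of {LAYOUT_NAMES}")
    hx, hy = working_range(geom)
    sx, sy = (1.0 - margin_frac) * hx, (1.0 - margin_frac) * hy
    if name == "TEST12":
        cols = np.array([-0.75, -0.25, 0.25, 0.75]) * sx
        rows = np.array([0.75, 0.0, -0.75]) * sy
        pts = [DegPoint(float(x), float(y)) for y in rows for x in cols]
        return CalibrationLayout(name, tuple(pts))
    center = [DegPoint(0.0, 0.0)]
    corners = [DegPoint(i * sx, j * sy) for i in (-1, 1) for j in (-1, 1)]
    cross = [DegPoint(i * sx, 0.0) for i in (-1, 1)] + [DegPoint(0.0, j * sy) for j in (-1, 1)]
    diag = [DegPoint(i * sx / 2.0, j * sy / 2.0) for i in (-1, 1) for j in (-1, 1)]
    pts = center + corners
    if name in ("9P", "13P"):
        pts += cross
    if name == "13P":
        pts += diag
    return CalibrationLayout(name, tuple(pts))


@dataclass(frozen=True)
class TargetObservation:
    """Aggregated gaze measurement at one calibration/test target."""

    target: DegPoint
    eye: str
    gaze_median: DegPoint
    error_vec: tuple[float, float]
    error_mag_deg: float
    n_samples: int


def aggregate_target(
    rec: GazeRecording,
    target,
    eye: str,
    discard_ms: float = 500.0,
) -> TargetObservation:
    """Median gaze over the dwell after discarding the initial transient.

    The first ``discard_ms`` of the recording (compensatory saccades toward
    the target) are dropped; the gaze position is the component-wise median
    of the remaining valid samples and the error is median minus target.
    """
    if rec.duration_ms <= discard_ms:
        raise InsufficientDataError(
            f"recording spans {rec.duration_ms:.0f} ms <= discard window {discard_ms:.0f} ms"
        )
    t, xy = rec.eye_positions(eye, valid_only=True)
    t0 = rec.t_ms[0]
    keep = t >= t0 + discard_ms
    if not keep.any():
        raise InsufficientDataError("no valid samples after the discard window")
    med = np.median(xy[keep], axis=0)
    tx, ty = float(target[0]), float(target[1])
    err = (float(med[0] - tx), float(med[1] - ty))
    return TargetObservation(
        target=DegPoint(tx, ty),
        eye=eye,
        gaze_median=DegPoint(float(med[0]), float(med[1])),
        error_vec=err,
        error_mag_deg=float(math.hypot(*err)),
        n_samples=int(keep.sum()),
    )


def flag_retries(observations, threshold_deg: float = 0.5) -> list[DegPoint]:
    """Targets whose error magnitude strictly exceeds the retry threshold.

    With observations from both eyes, a target is flagged if *either* eye
    exceeds the threshold.  Ties at the threshold pass.
    """
    flagged: list[DegPoint] = []
    for obs in observations:
        if obs.error_mag_deg > threshold_deg and obs.target not in flagged:
            flagged.append(obs.target)
    return flagged


def _biharm(r: np.ndarray) -> np.ndarray:
    """2D biharmonic radial basis g(r) = r^2 (ln r - 1), with g(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * (np.log(r[nz]) - 1.0)
    return out


class BiharmonicSurface(BaseEstimator):
    """Scattered-data interpolating surface over calibration targets.

    Fits one scalar field per output column (here: x- and y-corrections) as a
    constant term plus biharmonic radial basis weights centered on the target
    positions.  With ``ridge=0`` (default) the surface passes exactly through
    every observation; a positive ridge relaxes this to penalized smoothing.

    Attributes (after ``fit``)
    --------------------------
    points_ : (n, 2) target positions.
    means_ : (m,) per-output constant terms.
    weights_ : (n, m) radial basis weights.
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y) -> "BiharmonicSurface":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in surface fit input")
        # duplicate target positions make the interpolation system singular
        d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
        n = X.shape[0]
        off = ~np.eye(n, dtype=bool)
        if n > 1 and np.any(d2[off] < 1e-18):
            raise ValueError("duplicate target positions yield a singular system")
        self.points_ = X
        self.means_ = y.mean(axis=0)
        if n == 1:
            self.weights_ = np.zeros((1, y.shape[1]))
        else:
            G = _biharm(np.sqrt(d2))
            if self.ridge:
                G = G + self.ridge * np.eye(n)
            self.weights_ = np.linalg.solve(G, y - self.means_)
        self._tri = None
        if n >= 3:
            try:
                self._tri = Delaunay(X)
            except QhullError:
                self._tri = None  # degenerate (collinear) layouts have no hull
        return self

    def predict(self, X) -> np.ndarray:
        p = np.atleast_2d(np.asarray(X, dtype=float))
        r = np.sqrt(np.sum((p[:, None, :] - self.points_[None, :, :]) ** 2, axis=-1))
        return self.means_ + _biharm(r) @ self.weights_

    def in_hull(self, X) -> np.ndarray:
        """True where the query lies inside the convex hull of the targets."""
        p = np.atleast_2d(np.asarray(X, dtype=float))
        if self._tri is None:
            return np.zeros(len(p), dtype=bool)
        return self._tri.find_simplex(p) >= 0

    @property
    def hull_points_(self) -> np.ndarray:
        return self.points_

    def to_dict(self) -> dict:
        return {
            "ridge": self.ridge,
            "points": self.points_.tolist(),
            "means": self.means_.tolist(),
            "weights": self.weights_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiharmonicSurface":
        surf = cls(ridge=d.get("ridge", 0.0))
        surf.points_ = np.asarray(d["points"], dtype=float)
        surf.means_ = np.asarray(d["means"], dtype=float)
        surf.weights_ = np.asarray(d["weights"], dtype=float)
        surf._tri = None
        if len(surf.points_) >= 3:
            try:
                surf._tri = Delaunay(surf.points_)
            except QhullError:
                surf._tri = None
        return surf


def fit_surface(observations, ridge: float = 0.0, knots: str = "measured") -> BiharmonicSurface:
    """Fit the per-axis correction surfaces for one eye's observations.

    The surface is a function of *measured* gaze position (``knots =
    "measured"``, the default): its interpolation knots sit at the measured
    gaze medians, so subtracting the surface evaluated at the measured
    position corrects each calibration observation exactly.  With ``knots =
    "target"`` the surface is anchored at the displayed target positions
    instead; for errors much smaller than the surface length-scale the two
    differ only at second order.
    """
    obs = list(observations)
    if not obs:
        raise InsufficientDataError("at least one observation is required")
    if knots not in ("measured", "target"):
        raise ValueError(f"knots must be 'measured' or 'target', got {knots!r}")
    attr = "gaze_median" if knots == "measured" else "target"
    X = np.array([getattr(obs_i, attr) for obs_i in obs], dtype=float)
    y = np.array([obs_i.error_vec for obs_i in obs], dtype=float)
    return BiharmonicSurface(ridge=ridge).fit(X, y)


def evaluate_surface(surface: BiharmonicSurface, p) -> tuple[np.ndarray, bool]:
    """Correction vector (deg) at a point, plus an extrapolation flag.

    The flag is True when the point lies outside the convex hull of the
    calibration targets (the uncalibrated screen region).
    """
    q = np.asarray([p[0], p[1]], dtype=float)[None, :]
    vec = surface.predict(q)[0]
    inside = bool(surface.in_hull(q)[0])
    return vec, not inside


_MODE_EYES = {
    "binocular": ("left", "right"),
    "mono-left": ("left",),
    "mono-right": ("right",),
}


class GazeCalibrator(BaseEstimator):
    """Per-eye biharmonic gaze-correction estimator.

    ``fit`` consumes a calibration session (a sequence of ``(target,
    recording)`` pairs), aggregates each dwell by the median rule, flags
    targets violating the retry threshold, and fits one correction surface
    per eye and axis.  ``transform`` subtracts the surface, evaluated at each
    *measured* gaze position, from every sample of a recording.

    Parameters
    ----------
    mode : 'binocular', 'mono-left' or 'mono-right' — which eye(s) are
        calibrated.  Monocular mode carries exactly one eye's surface.
    discard_ms : initial dwell transient to discard before the median.
    retry_threshold_deg : per-target error above which a retry is flagged
        (strict inequality).
    ridge : smoothing parameter of the surfaces (0 = exact interpolation).

    Attributes (after ``fit``)
    --------------------------
    surfaces_ : dict eye -> fitted :class:`BiharmonicSurface`.
    observations_ : dict eye -> list of :class:`TargetObservation`.
    retry_targets_ : targets flagged by the retry rule.
    """

    def __init__(self, mode: str = "binocular", discard_ms: float = 500.0,
                 retry_threshold_deg: float = 0.5, ridge: float = 0.0):
        self.mode = mode
        self.discard_ms = discard_ms
        self.retry_threshold_deg = retry_threshold_deg
        self.ridge = ridge

    def fit(self, session, y=None) -> "GazeCalibrator":
        if self.mode not in _MODE_EYES:
            raise ValueError(f"mode must be one of {tuple(_MODE_EYES)}, got {self.mode!r}")
        eyes = _MODE_EYES[self.mode]
        self.observations_ = {eye: [] for eye in eyes}
        for target, rec in session:
            for eye in eyes:
                self.observations_[eye].append(
                    aggregate_target(rec, target, eye, discard_ms=self.discard_ms)
                )
        all_obs = list(itertools.chain.from_iterable(self.observations_.values()))
        self.retry_targets_ = flag_retries(all_obs, self.retry_threshold_deg)
        self.surfaces_ = {
            eye: fit_surface(obs, ridge=self.ridge) for eye, obs in self.observations_.items()
        }
        return self

    def transform(self, rec: GazeRecording) -> GazeRecording:
        """Apply the fitted correction to every valid sample of a recording."""
        if not hasattr(self, "surfaces_"):
            raise ValueError("GazeCalibrator is not fitted")
        df = rec.samples.copy()
        for eye in ("left", "right"):
            valid = df[f"{eye}_valid"] == 1
            if not valid.any():
                continue
            if eye not in self.surfaces_:
                raise ValueError(
                    f"recording carries valid {eye}-eye data but the calibration "
                    f"mode is {self.mode!r}"
                )
            pos = df.loc[valid, [f"{eye}_x_deg", f"{eye}_y_deg"]].to_numpy(dtype=float)
            corr = self.surfaces_[eye].predict(pos)
            df.loc[valid, [f"{eye}_x_deg", f"{eye}_y_deg"]] = pos - corr
        return GazeRecording(geometry=rec.geometry, samples=df, meta=dict(rec.meta))

    def run_test(self, test_session) -> pd.DataFrame:
        """Residual errors at test targets, uncorrected and corrected.

        Each test dwell is aggregated with the same median rule, before and
        after correction.  Returns one row per (target, eye).
        """
        rows = []
        eyes = _MODE_EYES[self.mode]
        for target, rec in test_session:
            corrected = self.transform(rec)
            for eye in eyes:
                raw = aggregate_target(rec, target, eye, discard_ms=self.discard_ms)
                cor = aggregate_target(corrected, target, eye, discard_ms=self.discard_ms)
                rows.append(
                    {
                        "target_x_deg": float(target[0]),
                        "target_y_deg": float(target[1]),
                        "eye": eye,
                        "uncorrected_deg": raw.error_mag_deg,
                        "corrected_deg": cor.error_mag_deg,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "discard_ms": self.discard_ms,
            "retry_threshold_deg": self.retry_threshold_deg,
            "ridge": self.ridge,
            "surfaces": {eye: s.to_dict() for eye, s in self.surfaces_.items()},
            "retry_targets": [list(t) for t in self.retry_targets_],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GazeCalibrator":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        calib = cls(mode=d["mode"], discard_ms=d["discard_ms"],
                    retry_threshold_deg=d["retry_threshold_deg"], ridge=d["ridge"])
        calib.surfaces_ = {eye: BiharmonicSurface.from_dict(s) for eye, s in d["surfaces"].items()}
        calib.observations_ = {eye: [] for eye in calib.surfaces_}
        calib.retry_targets_ = [DegPoint(*t) for t in d["retry_targets"]]
        return calib


def apply_correction(rec: GazeRecording, result: GazeCalibrator) -> GazeRecording:
    """Functional alias for :meth:`GazeCalibrator.transform`."""
    return result.transform(rec)


def run_test(result: GazeCalibrator, test_session) -> pd.DataFrame:
    """Functional alias for :meth:`GazeCalibrator.run_test`."""
    return result.run_test(test_session)
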