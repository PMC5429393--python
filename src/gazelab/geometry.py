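"""Screen and viewing geometry for on-screen gaze data.

Angular coordinates are defined per axis from the metric offset of a point
relative to the screen center: a point at physical offset ``(dx, dy)`` mm maps
to ``(atan(dx/D), atan(dy/D))`` degrees, with ``D`` the perpendicular viewing
distance through the screen center (chin-rest assumption).  x is positive
rightward, y positive upward; screen pixel rows increase downward, so the
pixel conversion negates the vertical axis.  This per-axis gnomonic convention
is exactly invertible, which the pixel round-trip relies on.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ScreenGeometry",
    "DegPoint",
    "px_to_deg",
    "deg_to_px",
    "working_range",
    "angular_distance",
    "eccentricity",
    "vergence_angle",
    "latency_from_frames",
]


class DegPoint(NamedTuple):
    """On-screen position in degrees of visual angle (center origin, y up)."""

    x_deg: float
    y_deg: float


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen size, pixel resolution and perpendicular viewing distance.

    All lengths are millimetres.  The cyclopean eye is assumed to sit on the
    perpendicular through the screen center at ``viewing_distance_mm``.
    """

    width_mm: float
    height_mm: float
    res_x_px: int
    res_y_px: int
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "viewing_distance_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        for name in ("res_x_px", "res_y_px"):
            v = getattr(self, name)
            if not (int(v) == v and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def pitch_x_mm(self) -> float:
        return self.width_mm / self.res_x_px

    @property
    def pitch_y_mm(self) -> float:
        return self.height_mm / self.res_y_px

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        return cls(
            width_mm=float(d["width_mm"]),
            height_mm=float(d["height_mm"]),
            res_x_px=int(d["res_x_px"]),
            res_y_px=int(d["res_y_px"]),
            viewing_distance_mm=float(d["viewing_distance_mm"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScreenGeometry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _check_finite(*values: float) -> None:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinate input")


def px_to_deg(p_px, geom: ScreenGeometry) -> DegPoint:
    """Convert a (possibly fractional) pixel coordinate to degrees.

    Pixel coordinates are continuous with the origin at the top-left screen
    corner; the screen center is at ``(res_x/2, res_y/2)``.  Points may lie
    outside the screen.
    """
    px_x, px_y = float(p_px[0]), float(p_px[1])
    _check_finite(px_x, px_y)
    dx_mm = (px_x - geom.res_x_px / 2.0) * geom.pitch_x_mm
    dy_mm = (geom.res_y_px / 2.0 - px_y) * geom.pitch_y_mm
    d = geom.viewing_distance_mm
    return DegPoint(math.degrees(math.atan(dx_mm / d)), math.degrees(math.atan(dy_mm / d)))


def deg_to_px(p_deg, geom: ScreenGeometry) -> tuple[float, float]:
    """Exact inverse of :func:`px_to_deg`."""
    x_deg, y_deg = float(p_deg[0]), float(p_deg[1])
    _check_finite(x_deg, y_deg)
    d = geom.viewing_distance_mm
    dx_mm = d * math.tan(math.radians(x_deg))
    dy_mm = d * math.tan(math.radians(y_deg))
    px_x = dx_mm / geom.pitch_x_mm + geom.res_x_px / 2.0
    px_y = geom.res_y_px / 2.0 - dy_mm / geom.pitch_y_mm
    return (px_x, px_y)


def working_range(geom: ScreenGeometry) -> tuple[float, float]:
    """Half-angles (deg) subtended by the right-edge and top-edge midpoints.

    For a 24-inch 16:9 screen viewed at 800 mm this reproduces the familiar
    ±18° horizontal / ±10.5° vertical angular workspace of a desktop tracker.
    """
    d = geom.viewing_distance_mm
    return (
        math.degrees(math.atan(geom.width_mm / 2.0 / d)),
        math.degrees(math.atan(geom.height_mm / 2.0 / d)),
    )


def _direction(p: DegPoint, geom: ScreenGeometry) -> np.ndarray:
    """Unit 3D gaze direction from the cyclopean eye through an on-screen point."""
    d = geom.viewing_distance_mm
    v = np.array(
        [
            d * math.tan(math.radians(p[0])),
            d * math.tan(math.radians(p[1])),
            d,
        ]
    )
    return v / np.linalg.norm(v)


def angular_distance(a, b, geom: ScreenGeometry) -> float:
    """True 3D angle (deg) between the gaze rays through two on-screen points."""
    _check_finite(a[0], a[1], b[0], b[1])
    va, vb = _direction(a, geom), _direction(b, geom)
    # atan2 of cross/dot is numerically stable for near-identical directions
    return math.degrees(math.atan2(np.linalg.norm(np.cross(va, vb)), float(np.dot(va, vb))))


def eccentricity(p, geom: ScreenGeometry) -> float:
    """Angular distance (deg) of an on-screen point from the screen center."""
    return angular_distance(p, DegPoint(0.0, 0.0), geom)


def vergence_angle(ipd_mm: float, fixation_distance_mm: float) -> float:
    """Vergence demand (deg) of a fixation at a given distance.

    ``2 * atan(ipd / (2 * distance))``: the angle between the two eyes' lines
    of sight when both are pointed at a target straight ahead at
    ``fixation_distance_mm``.  Strictly decreasing in distance, tending to
    zero at infinity.
    """
    if not (ipd_mm > 0 and fixation_distance_mm > 0):
        raise ValueError("ipd_mm and fixation_distance_mm must be positive")
    return math.degrees(2.0 * math.atan(ipd_mm / (2.0 * fixation_distance_mm)))


def latency_from_frames(n_frames: int, camera_fps: float) -> float:
    """Latency (ms) from a count of elapsed camera frames."""
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    if not camera_fps > 0:
        raise ValueError("camera_fps must be positive")
    return n_frames * 1000.0 / camera_fps
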