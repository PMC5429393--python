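"""Data model and readers/writers for gaze recordings and trial annotations.

A recording is a time-ordered table of binocular gaze samples in *degrees*
(geometry-portable; the screen geometry travels in a sidecar JSON config).
The CSV dialect is plain comma-separated UTF-8 with header::

    t_ms,left_x_deg,left_y_deg,right_x_deg,right_y_deg,left_valid,right_valid,
    eye_lx_mm,eye_ly_mm,eye_lz_mm,eye_rx_mm,eye_ry_mm,eye_rz_mm

Booleans are written as 0/1, missing values as empty cells.  A missing eye
position always carries a false validity flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "GazeFormatError",
    "GazeRecording",
    "GAZE_COLUMNS",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "slice_by_annotation",
    "drop_invalid",
    "save_session_config",
    "load_session_config",
]

GAZE_COLUMNS = [
    "t_ms",
    "left_x_deg",
    "left_y_deg",
    "right_x_deg",
    "right_y_deg",
    "left_valid",
    "right_valid",
    "eye_lx_mm",
    "eye_ly_mm",
    "eye_lz_mm",
    "eye_rx_mm",
    "eye_ry_mm",
    "eye_rz_mm",
]

#: columns that must be present in a gaze CSV; 3D eye positions are optional
REQUIRED_COLUMNS = GAZE_COLUMNS[:7]

ANNOTATION_COLUMNS = ["trial", "label", "t_ms", "target_x_deg", "target_y_deg"]

VIEWING_CONDITIONS = ("binocular", "mono-left", "mono-right")


class GazeFormatError(ValueError):
    """Raised when a gaze or annotation file violates the dialect contract."""


@dataclass
class GazeRecording:
    """An ordered, time-stamped binocular gaze recording.

    ``samples`` is a DataFrame with the columns of :data:`GAZE_COLUMNS`;
    timestamps are strictly increasing milliseconds.  ``meta`` holds subject /
    session identifiers, the viewing condition and the nominal sampling rate.
    """

    geometry: ScreenGeometry
    samples: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.samples.copy()
        for col in GAZE_COLUMNS:
            if col not in df.columns:
                df[col] = 0.0 if col in ("left_valid", "right_valid") else np.nan
        df = df[GAZE_COLUMNS].reset_index(drop=True)
        t = df["t_ms"].to_numpy(dtype=float)
        if len(t) > 1:
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                raise GazeFormatError(
                    f"timestamps not strictly increasing at row {bad[0] + 1} "
                    f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
                )
        # enforce: a missing eye position implies validity false
        for eye in ("left", "right"):
            missing = df[[f"{eye}_x_deg", f"{eye}_y_deg"]].isna().any(axis=1)
            flags = df[f"{eye}_valid"].fillna(0).astype(float) != 0
            flags &= ~missing
            df[f"{eye}_valid"] = flags.astype(int)
            df.loc[~flags, [f"{eye}_x_deg", f"{eye}_y_deg"]] = np.nan
        cond = self.meta.get("condition", "binocular")
        if cond not in VIEWING_CONDITIONS:
            raise ValueError(f"unknown viewing condition {cond!r}")
        if cond == "mono-left" and df["right_valid"].any():
            raise GazeFormatError("mono-left recording carries valid right-eye samples")
        if cond == "mono-right" and df["left_valid"].any():
            raise GazeFormatError("mono-right recording carries valid left-eye samples")
        self.samples = df

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t_ms(self) -> np.ndarray:
        return self.samples["t_ms"].to_numpy(dtype=float)

    @property
    def duration_ms(self) -> float:
        t = self.t_ms
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def eye_positions(self, eye: str, valid_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Return (t, xy) arrays for one eye, optionally restricted to valid samples."""
        if eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
        df = self.samples
        if valid_only:
            df = df[df[f"{eye}_valid"] == 1]
        t = df["t_ms"].to_numpy(dtype=float)
        xy = df[[f"{eye}_x_deg", f"{eye}_y_deg"]].to_numpy(dtype=float)
        return t, xy

    def validity_rate(self, eye: str) -> float:
        if len(self.samples) == 0:
            return float("nan")
        return float(self.samples[f"{eye}_valid"].mean())


def read_recording(path, geometry: ScreenGeometry, meta: dict | None = None) -> GazeRecording:
    """Read a gaze CSV in the package dialect.

    Non-finite gaze fields become missing with validity false.  Missing
    required columns and non-monotonic timestamps raise
    :class:`GazeFormatError` (the latter naming the first offending row).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"missing required columns: {missing}")
    return GazeRecording(geometry=geometry, samples=df, meta=dict(meta or {}))


def write_recording(rec: GazeRecording, path) -> None:
    """Write a recording to CSV (deterministic column order, 0/1 flags)."""
    df = rec.samples.copy()
    df["left_valid"] = df["left_valid"].astype(int)
    df["right_valid"] = df["right_valid"].astype(int)
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise GazeFormatError(f"missing annotation columns: {missing}")
    for c in ("target_x_deg", "target_y_deg"):
        if c not in df.columns:
            df[c] = np.nan
    return df[ANNOTATION_COLUMNS]


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def slice_by_annotation(
    rec: GazeRecording,
    annotations: pd.DataFrame,
    label: str,
    pre_ms: float,
    post_ms: float,
) -> list[GazeRecording]:
    """Cut one time-window per matching annotation, re-based so the event is t=0.

    The window is ``[-pre_ms, +post_ms]`` around each annotation timestamp.
    Slices near the recording boundary are simply shorter; slices may be empty.
    """
    matches = annotations[annotations["label"] == label]
    if len(matches) == 0:
        raise KeyError(f"no annotations with label {label!r}")
    out = []
    t = rec.t_ms
    for _, row in matches.iterrows():
        t0 = float(row["t_ms"])
        mask = (t >= t0 - pre_ms) & (t <= t0 + post_ms)
        df = rec.samples[mask].copy()
        df["t_ms"] = df["t_ms"] - t0
        meta = dict(rec.meta)
        meta["trial"] = row["trial"]
        if np.isfinite(row.get("target_x_deg", np.nan)):
            meta["target"] = (float(row["target_x_deg"]), float(row["target_y_deg"]))
        out.append(GazeRecording(geometry=rec.geometry, samples=df, meta=meta))
    return out


def drop_invalid(rec: GazeRecording, eye: str = "both") -> GazeRecording:
    """Remove samples whose selected eye(s) are invalid, preserving order."""
    df = rec.samples
    if eye == "left":
        mask = df["left_valid"] == 1
    elif eye == "right":
        mask = df["right_valid"] == 1
    elif eye == "both":
        mask = (df["left_valid"] == 1) & (df["right_valid"] == 1)
    else:
        raise ValueError(f"eye must be 'left', 'right' or 'both', got {eye!r}")
    return GazeRecording(geometry=rec.geometry, samples=df[mask], meta=dict(rec.meta))


def save_session_config(path, geometry: ScreenGeometry, condition: str = "binocular",
                        nominal_rate_hz: float = 55.0, **extra) -> None:
    cfg = {"geometry": geometry.to_dict(), "condition": condition,
           "nominal_rate_hz": nominal_rate_hz, **extra}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2)


def load_session_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    cfg["geometry"] = ScreenGeometry.from_dict(cfg["geometry"])
    return cfg
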