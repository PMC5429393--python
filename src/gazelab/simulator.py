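"""Synthetic binocular eye tracker and oculomotor-event generator.

Ground truth is always known, so every downstream module (calibration,
quality metrics, event detection) can be validated without hardware or human
subjects.  The simulator emulates a consumer-grade ~55-60 Hz binocular
tracker:

* a smooth, per-eye systematic *bias field* over the workspace (sum of
  Gaussian bumps plus a weak affine trend) — what the calibration surface
  must recover;
* a skewed per-fixation error offset (Gamma-distributed magnitude, uniform
  direction) emulating the left-skewed / long-right-tailed angular error
  histograms of such devices;
* per-sample Gaussian precision noise, inter-sample-interval jitter and
  dropout;
* scripted oculomotor events: fixations, raised-cosine saccades, constant
  velocity pursuit ramps and first-order exponential vergence steps applied
  antisymmetrically to the two eyes' horizontal angles.

All randomness flows from explicit seeds; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry
from .io import GAZE_COLUMNS, GazeRecording

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "PursuitEvent",
    "VergenceStepEvent",
    "OculomotorScript",
    "ScriptTrace",
    "true_gaze_trace",
    "BiasField",
    "make_bias_field",
    "make_bias_pair",
    "NoiseModel",
    "simulate_recording",
    "simulate_calibration_session",
    "default_geometry",
]


def default_geometry() -> ScreenGeometry:
    """A 24-inch 16:9 screen (531.3 x 298.9 mm, 1920x1080) viewed at 800 mm."""
    return ScreenGeometry(531.3, 298.9, 1920, 1080, 800.0)


# ---------------------------------------------------------------------------
# scripted oculomotor events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixationEvent:
    position: tuple[float, float]
    duration_ms: float


@dataclass(frozen=True)
class SaccadeEvent:
    """Ballistic gaze shift with a raised-cosine velocity profile.

    v(t) = Vp (1 - cos(2 pi t / T)) / 2 with Vp = 2A/T, so a 10 deg, 50 ms
    saccade peaks at exactly 400 deg/s, consistent with main-sequence
    kinematics of saccades of this size.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    duration_ms: float
    latency_ms: float = 0.0


@dataclass(frozen=True)
class PursuitEvent:
    """Constant-velocity target ramp tracked at a given gain after a latency."""

    start: tuple[float, float]
    velocity_deg_s: tuple[float, float]
    duration_ms: float
    latency_ms: float = 0.0
    gain: float = 1.0


@dataclass(frozen=True)
class VergenceStepEvent:
    """Disparity step driving a first-order exponential vergence response.

    The vergence change is applied antisymmetrically to the two eyes'
    horizontal angles: convergence positive means the left eye rotates
    rightward and the right eye leftward, each by half the disparity.
    """

    disparity_deg: float
    duration_ms: float
    latency_ms: float = 0.0
    time_constant_ms: float = 60.0


Event = FixationEvent | SaccadeEvent | PursuitEvent | VergenceStepEvent


@dataclass(frozen=True)
class OculomotorScript:
    """An ordered, contiguous sequence of oculomotor events."""

    events: tuple[Event, ...]

    def __init__(self, events: Sequence[Event]):
        if not events:
            raise ValueError("script must contain at least one event")
        for ev in events:
            if ev.duration_ms <= 0:
                raise ValueError("event durations must be positive")
        object.__setattr__(self, "events", tuple(events))

    @property
    def duration_ms(self) -> float:
        return float(sum(self._span(ev) for ev in self.events))

    @staticmethod
    def _span(ev: Event) -> float:
        lat = getattr(ev, "latency_ms", 0.0)
        return lat + ev.duration_ms


def _raised_cosine_pos(frac: np.ndarray) -> np.ndarray:
    """Normalized displacement of a raised-cosine velocity saccade, frac in [0,1]."""
    return frac - np.sin(2.0 * np.pi * frac) / (2.0 * np.pi)


class ScriptTrace:
    """Continuous-time noiseless binocular gaze trajectory compiled from a script.

    Calling the trace with an array of times (ms) returns ``(left, right)``
    position arrays of shape (n, 2) in degrees.  Conjugate position and
    vergence state are tracked separately; vergence is added as ±v/2 to the
    two eyes' horizontal angles.
    """

    def __init__(self, script: OculomotorScript):
        self.script = script
        self.duration_ms = script.duration_ms
        # compile segment table: (t0, t1, event, conj_at_t0, verg_at_t0)
        self._segments = []
        t0 = 0.0
        conj = None
        verg = 0.0
        for ev in script.events:
            if conj is None:
                conj = np.asarray(getattr(ev, "position", getattr(ev, "start", (0.0, 0.0))), float)
            t1 = t0 + OculomotorScript._span(ev)
            self._segments.append((t0, t1, ev, conj.copy(), verg))
            conj, verg = self._end_state(ev, conj, verg)
            t0 = t1
        self._final_conj, self._final_verg = conj, verg

    @staticmethod
    def _end_state(ev: Event, conj: np.ndarray, verg: float):
        if isinstance(ev, FixationEvent):
            return np.asarray(ev.position, float), verg
        if isinstance(ev, SaccadeEvent):
            return np.asarray(ev.end, float), verg
        if isinstance(ev, PursuitEvent):
            v = np.asarray(ev.velocity_deg_s, float)
            end = np.asarray(ev.start, float) + ev.gain * v * ev.duration_ms / 1000.0
            return end, verg
        if isinstance(ev, VergenceStepEvent):
            step = ev.disparity_deg * (1.0 - math.exp(-ev.duration_ms / ev.time_constant_ms))
            return conj, verg + step
        raise TypeError(f"unknown event type {type(ev)!r}")

    def _eval_segment(self, ev: Event, tau: np.ndarray, conj0: np.ndarray, verg0: float):
        """Conjugate position (n,2) and vergence (n,) within one event, tau >= 0."""
        n = len(tau)
        conj = np.tile(conj0, (n, 1))
        verg = np.full(n, verg0)
        lat = getattr(ev, "latency_ms", 0.0)
        moving = tau > lat
        tm = np.clip(tau - lat, 0.0, ev.duration_ms)
        if isinstance(ev, FixationEvent):
            conj = np.tile(np.asarray(ev.position, float), (n, 1))
        elif isinstance(ev, SaccadeEvent):
            a = np.asarray(ev.start, float)
            b = np.asarray(ev.end, float)
            frac = _raised_cosine_pos(tm / ev.duration_ms)
            conj = np.tile(a, (n, 1))
            conj[moving] = a + np.outer(frac[moving], b - a)
        elif isinstance(ev, PursuitEvent):
            a = np.asarray(ev.start, float)
            v = np.asarray(ev.velocity_deg_s, float) * ev.gain
            conj = np.tile(a, (n, 1))
            conj[moving] = a + np.outer(tm[moving] / 1000.0, v)
        elif isinstance(ev, VergenceStepEvent):
            verg = verg0 + np.where(
                moving,
                ev.disparity_deg * (1.0 - np.exp(-tm / ev.time_constant_ms)),
                0.0,
            )
        return conj, verg

    def __call__(self, t_ms) -> tuple[np.ndarray, np.ndarray]:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        conj = np.tile(self._final_conj, (len(t), 1))
        verg = np.full(len(t), self._final_verg)
        for t0, t1, ev, c0, v0 in self._segments:
            m = (t >= t0) & (t < t1) if t1 < self.duration_ms else (t >= t0)
            if not m.any():
                continue
            c, v = self._eval_segment(ev, t[m] - t0, c0, v0)
            conj[m], verg[m] = c, v
        left = conj.copy()
        right = conj.copy()
        left[:, 0] += verg / 2.0
        right[:, 0] -= verg / 2.0
        return left, right


def true_gaze_trace(script: OculomotorScript, rate_hz: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the noiseless binocular trajectory at a nominal rate.

    Returns ``(t_ms, left, right)`` with positions in degrees.
    """
    if not rate_hz > 0:
        raise ValueError("rate_hz must be positive")
    trace = ScriptTrace(script)
    n = max(2, int(math.floor(trace.duration_ms * rate_hz / 1000.0)))
    t = np.arange(n) * (1000.0 / rate_hz)
    left, right = trace(t)
    return t, left, right


# ---------------------------------------------------------------------------
# device error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasField:
    """Smooth 2D vector field giving systematic gaze offset (deg) vs true position.

    Sum of K isotropic Gaussian bumps with vector amplitudes plus an affine
    term, rescaled at construction so the maximum offset magnitude over the
    workspace is the declared ``amplitude_bound_deg``.
    """

    centers: np.ndarray          # (K, 2)
    amplitudes: np.ndarray       # (K, 2)
    widths: np.ndarray           # (K,)
    affine: np.ndarray           # (2, 2), applied to position
    amplitude_bound_deg: float

    def __call__(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.affine.T
        for c, a, w in zip(self.centers, self.amplitudes, self.widths):
            r2 = np.sum((p - c) ** 2, axis=1)
            out = out + np.outer(np.exp(-r2 / (2.0 * w * w)), a)
        return out


def make_bias_field(
    seed: int,
    amplitude_deg: float = 1.0,
    k_bumps: int = 4,
    extent_deg: tuple[float, float] = (18.0, 10.5),
    width_range_deg: tuple[float, float] = (8.0, 16.0),
    affine_frac: float = 0.2,
) -> BiasField:
    """Draw a random smooth bias field, deterministic in ``seed``.

    Bump widths default to at least the inter-target spacing of a 13-point
    calibration layout on a standard workspace, so the field is recoverable
    by surface interpolation at that layout scale.  Zero amplitude yields the
    identically zero field.
    """
    if amplitude_deg < 0:
        raise ValueError("amplitude_deg must be non-negative")
    rng = np.random.default_rng(seed)
    hx, hy = extent_deg
    centers = rng.uniform([-hx, -hy], [hx, hy], size=(k_bumps, 2))
    theta = rng.uniform(0, 2 * np.pi, size=k_bumps)
    mags = rng.uniform(0.5, 1.0, size=k_bumps)
    amplitudes = np.column_stack([mags * np.cos(theta), mags * np.sin(theta)])
    widths = rng.uniform(*width_range_deg, size=k_bumps)
    affine = rng.uniform(-1.0, 1.0, size=(2, 2)) * (affine_frac / max(hx, hy))
    raw = BiasField(centers, amplitudes, widths, affine, amplitude_bound_deg=np.inf)
    # rescale so the max magnitude over a dense workspace grid equals amplitude_deg
    gx, gy = np.meshgrid(np.linspace(-hx, hx, 121), np.linspace(-hy, hy, 81))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    peak = float(np.max(np.linalg.norm(raw(grid), axis=1)))
    scale = 0.0 if (peak == 0.0 or amplitude_deg == 0.0) else amplitude_deg / peak
    return BiasField(
        centers=centers,
        amplitudes=amplitudes * scale,
        widths=widths,
        affine=affine * scale,
        amplitude_bound_deg=float(amplitude_deg),
    )


def make_bias_pair(
    seed: int,
    amplitude_deg: float = 1.0,
    k_bumps: int = 4,
    nondominant_scale: float = 1.3,
    dominant_eye: str = "right",
    **kwargs,
) -> dict[str, BiasField]:
    """Independent left/right bias fields, the non-dominant eye's scaled up.

    Eye dominance shows up in binocular gaze data as a larger systematic error
    of the non-dominant eye; the default scale factor is 1.3.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    fields = {}
    for eye, child in zip(("left", "right"), ss):
        amp = amplitude_deg if eye == dominant_eye else amplitude_deg * nondominant_scale
        fields[eye] = make_bias_field(int(child.generate_state(1)[0] % (2**31)),
                                      amplitude_deg=amp, k_bumps=k_bumps, **kwargs)
    return fields


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic error model of the simulated tracker.

    precision_sd_deg : per-axis SD of Gaussian sample noise (precision).
    skew_shape, skew_scale_deg : Gamma(shape, scale) magnitude of a constant
        per-fixation offset with uniform random direction, emulating a skewed
        (long right tail) angular error distribution.  Shape 0 disables it.
    isi_jitter_ms : SD of inter-sample-interval jitter.
    dropout_rate : per-eye probability a sample is flagged invalid.
    """

    precision_sd_deg: float = 0.15
    skew_shape: float = 0.0
    skew_scale_deg: float = 0.15
    isi_jitter_ms: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.precision_sd_deg, self.skew_shape, self.skew_scale_deg,
               self.isi_jitter_ms) < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")


def _as_bias_dict(bias) -> dict[str, BiasField | None]:
    if bias is None:
        return {"left": None, "right": None}
    if isinstance(bias, BiasField):
        return {"left": bias, "right": bias}
    if isinstance(bias, dict):
        return {"left": bias.get("left"), "right": bias.get("right")}
    left, right = bias
    return {"left": left, "right": right}


def simulate_recording(
    trace,
    bias=None,
    noise: NoiseModel | None = None,
    rate_hz: float = 55.0,
    seed: int = 0,
    geometry: ScreenGeometry | None = None,
    meta: dict | None = None,
    duration_ms: float | None = None,
) -> GazeRecording:
    """Sample a noisy recording of a true gaze trace.

    ``trace`` is a :class:`ScriptTrace` (or any callable of time returning
    per-eye positions, with a ``duration_ms`` attribute unless ``duration_ms``
    is given).  Measured gaze = true gaze + bias(true position) + per-fixation
    skewed offset + Gaussian sample noise; sample times carry ISI jitter;
    dropouts are flagged invalid.  Bit-reproducible given ``seed``.
    """
    noise = noise or NoiseModel()
    geometry = geometry or default_geometry()
    meta = dict(meta or {})
    meta.setdefault("condition", "binocular")
    meta.setdefault("nominal_rate_hz", rate_hz)
    dur = duration_ms if duration_ms is not None else trace.duration_ms
    rng = np.random.default_rng(seed)

    isi = 1000.0 / rate_hz
    n = max(2, int(math.floor(dur / isi)))
    steps = np.full(n, isi)
    if noise.isi_jitter_ms > 0:
        steps = steps + rng.normal(0.0, noise.isi_jitter_ms, size=n)
        steps = np.maximum(steps, 0.05)  # keep timestamps strictly increasing
    t = np.concatenate([[0.0], np.cumsum(steps[:-1])])

    left_true, right_true = trace(t)
    fields = _as_bias_dict(bias)
    cond = meta["condition"]
    df = pd.DataFrame({c: np.nan for c in GAZE_COLUMNS}, index=range(n))
    df["t_ms"] = t
    for eye, true in (("left", left_true), ("right", right_true)):
        if (cond == "mono-left" and eye == "right") or (cond == "mono-right" and eye == "left"):
            df[f"{eye}_valid"] = 0
            continue
        measured = true.copy()
        f = fields[eye]
        if f is not None:
            measured = measured + f(true)
        if noise.skew_shape > 0 and noise.skew_scale_deg > 0:
            mag = rng.gamma(noise.skew_shape, noise.skew_scale_deg)
            ang = rng.uniform(0, 2 * np.pi)
            measured = measured + mag * np.array([np.cos(ang), np.sin(ang)])
        if noise.precision_sd_deg > 0:
            measured = measured + rng.normal(0.0, noise.precision_sd_deg, size=measured.shape)
        valid = np.ones(n, dtype=int)
        if noise.dropout_rate > 0:
            valid = (rng.random(n) >= noise.dropout_rate).astype(int)
            measured[valid == 0] = np.nan
        df[f"{eye}_x_deg"] = measured[:, 0]
        df[f"{eye}_y_deg"] = measured[:, 1]
        df[f"{eye}_valid"] = valid
    return GazeRecording(geometry=geometry, samples=df, meta=meta)


class _CompensatoryFixation:
    """Fixation trace with an initial compensatory-saccade transient.

    The gaze starts offset from the target and settles with a raised-cosine
    window that reaches exactly zero at ``settle_ms`` — data earlier than the
    standard 0.5 s discard window are contaminated, later data are clean.
    """

    def __init__(self, position, offset_vec, duration_ms, settle_ms=300.0):
        self.position = np.asarray(position, float)
        self.offset = np.asarray(offset_vec, float)
        self.duration_ms = float(duration_ms)
        self.settle_ms = float(settle_ms)

    def __call__(self, t_ms):
        t = np.atleast_1d(np.asarray(t_ms, float))
        w = np.where(t < self.settle_ms,
                     0.5 * (1.0 + np.cos(np.pi * np.clip(t, 0, self.settle_ms) / self.settle_ms)),
                     0.0)
        pos = self.position + np.outer(w, self.offset)
        return pos, pos.copy()


def simulate_calibration_session(
    layout,
    bias=None,
    noise: NoiseModel | None = None,
    rate_hz: float = 55.0,
    seed: int = 0,
    dwell_ms: float = 2000.0,
    geometry: ScreenGeometry | None = None,
    mode: str = "binocular",
    compensatory: bool = True,
    fixation_disparity_deg: float = 0.0,
) -> list[tuple[tuple[float, float], GazeRecording]]:
    """Simulate one calibration (or test) session over a target layout.

    Targets are presented in a seed-determined random order for ``dwell_ms``
    each; the first part of each dwell may contain a compensatory-saccade
    transient (1-2 deg, settled within 300 ms).  In binocular viewing a
    fixation-disparity offset (``±fixation_disparity_deg/2`` on the two eyes'
    horizontal angles) models the behavioral misalignment of binocular
    fixation; monocular viewing records only the viewing eye, fixating
    accurately.  Returns ``[(target, recording), ...]`` in presentation order.
    """
    noise = noise or NoiseModel()
    geometry = geometry or default_geometry()
    targets = getattr(layout, "targets", layout)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    children = np.random.SeedSequence(seed).spawn(len(targets))
    out = []
    for k, idx in enumerate(order):
        tgt = tuple(np.asarray(targets[idx], float))
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        if compensatory:
            mag = rng.uniform(1.0, 2.0)
            ang = rng.uniform(0, 2 * np.pi)
            trace = _CompensatoryFixation(tgt, mag * np.array([np.cos(ang), np.sin(ang)]),
                                          dwell_ms)
        else:
            trace = ScriptTrace(OculomotorScript([FixationEvent(tgt, dwell_ms)]))
        if mode == "binocular" and fixation_disparity_deg != 0.0:
            base = trace
            d = fixation_disparity_deg / 2.0

            def disparate(t_ms, _base=base, _d=d):
                left, right = _base(t_ms)
                left = left.copy()
                right = right.copy()
                left[:, 0] += _d
                right[:, 0] -= _d
                return left, right

            trace = disparate
        rec = simulate_recording(
            trace, bias=bias, noise=noise, rate_hz=rate_hz, seed=child_seed,
            geometry=geometry, meta={"condition": mode, "target": tgt},
            duration_ms=dwell_ms,
        )
        out.append((tgt, rec))
    return out
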