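"""Gaze data quality metrics and statistical comparisons.

Accuracy is the systematic angular error during fixation of a known target;
precision is the dispersion of samples about their fixation centroid.
Because angular errors are skewed (long right tail), eccentricity profiles
are summarized by median and inter-quartile range; whole-cohort tables use
mean ± SD.  Sampling statistics are computed from inter-sample intervals, and
calibration repeatability is quantified by Pearson correlation between
correction surfaces sampled over the calibrated screen area.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import BiharmonicSurface
from .geometry import ScreenGeometry, eccentricity

__all__ = [
    "accuracy",
    "precision",
    "precision_per_axis",
    "bin_by_eccentricity",
    "sampling_stats",
    "surface_correlation",
    "repeatability_correlations",
    "paired_t_one_tailed",
    "compare_calibrations",
    "QualityReport",
    "quality_report",
]


def accuracy(errors) -> tuple[float, float, float, float]:
    """(median, IQR, min, max) of a set of angular error magnitudes (deg).

    Quartiles use linear interpolation between order statistics.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("accuracy requires at least one error value")
    q1, med, q3 = np.percentile(e, [25.0, 50.0, 75.0])
    return float(med), float(q3 - q1), float(e.min()), float(e.max())


def precision(samples) -> float:
    """SD of gaze samples about their centroid, axes combined in quadrature.

    ``sqrt(var_x + var_y)`` with population variances; translation-invariant
    and linear in the noise SD.
    """
    xy = np.atleast_2d(np.asarray(samples, dtype=float))
    if xy.shape[0] < 2:
        raise ValueError("precision requires at least two samples")
    return float(np.sqrt(np.var(xy[:, 0]) + np.var(xy[:, 1])))


def precision_per_axis(samples) -> tuple[float, float]:
    xy = np.atleast_2d(np.asarray(samples, dtype=float))
    if xy.shape[0] < 2:
        raise ValueError("precision requires at least two samples")
    return float(np.std(xy[:, 0])), float(np.std(xy[:, 1]))


def bin_by_eccentricity(observations: pd.DataFrame, geom: ScreenGeometry,
                        round_deg: float = 0.1) -> dict[float, pd.DataFrame]:
    """Group a per-target table by target eccentricity.

    ``observations`` needs ``target_x_deg``/``target_y_deg`` columns.
    Eccentricities are rounded (default 0.1 deg) to merge floating-point-equal
    radii; groups are returned in ascending eccentricity order.
    """
    df = observations.copy()
    ecc = [
        round(eccentricity((x, y), geom) / round_deg) * round_deg
        for x, y in zip(df["target_x_deg"], df["target_y_deg"])
    ]
    df["eccentricity_deg"] = np.round(ecc, 6)
    return {float(k): g.drop(columns="eccentricity_deg")
            for k, g in sorted(df.groupby("eccentricity_deg"))}


def sampling_stats(timestamps) -> tuple[float, float, float]:
    """(median ISI ms, ISI IQR ms, median rate Hz) of a timestamp sequence."""
    t = np.asarray(timestamps, dtype=float)
    if t.size < 2:
        raise ValueError("sampling_stats requires at least two timestamps")
    isi = np.diff(t)
    if np.any(isi <= 0):
        raise ValueError("timestamps must be strictly increasing")
    q1, med, q3 = np.percentile(isi, [25.0, 50.0, 75.0])
    return float(med), float(q3 - q1), float(1000.0 / med)


def _hull_grid(surfaces: list[BiharmonicSurface], grid: tuple[int, int]) -> np.ndarray:
    pts = np.vstack([s.hull_points_ for s in surfaces])
    nx, ny = grid
    gx, gy = np.meshgrid(
        np.linspace(pts[:, 0].min(), pts[:, 0].max(), nx),
        np.linspace(pts[:, 1].min(), pts[:, 1].max(), ny),
    )
    q = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.ones(len(q), dtype=bool)
    for s in surfaces:
        inside &= s.in_hull(q)
    return q[inside]


def surface_correlation(surf_a: BiharmonicSurface, surf_b: BiharmonicSurface,
                        grid: tuple[int, int] = (25, 25)) -> tuple[float, float]:
    """Pearson correlation of two correction surfaces, per axis.

    Both surfaces are sampled on the same regular grid restricted to the
    interior of their common calibration hull.
    """
    q = _hull_grid([surf_a, surf_b], grid)
    if len(q) < 3:
        raise ValueError("hull interiors do not overlap on the grid")
    va, vb = surf_a.predict(q), surf_b.predict(q)
    out = []
    for axis in (0, 1):
        if np.std(va[:, axis]) == 0 or np.std(vb[:, axis]) == 0:
            raise ValueError("correlation undefined for a constant correction field")
        out.append(float(stats.pearsonr(va[:, axis], vb[:, axis]).statistic))
    return out[0], out[1]


def repeatability_correlations(surfaces, grid: tuple[int, int] = (25, 25)) -> pd.DataFrame:
    """All pairwise surface correlations among repeated calibrations.

    Four repetitions yield C(4,2) = 6 correlation estimates (per axis), the
    standard bookkeeping for calibration repeatability.
    """
    surfaces = list(surfaces)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(surfaces), 2):
        rho_x, rho_y = surface_correlation(a, b, grid)
        rows.append({"rep_a": i, "rep_b": j, "rho_x": rho_x, "rho_y": rho_y})
    return pd.DataFrame(rows)


def paired_t_one_tailed(a, b) -> tuple[float, int, float]:
    """Paired one-tailed t-test of mean(a - b) > 0.

    Returns (t, df, p) with sample SD and df = n - 1.  All-zero differences
    give (0, df, 0.5); zero variance with nonzero mean gives ±inf and a
    degenerate p of 0 or 1 by sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test requires two equal-length arrays of size >= 2")
    d = a - b
    n = d.size
    m = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if m == 0:
            return 0.0, n - 1, 0.5
        t = math.inf if m > 0 else -math.inf
        return t, n - 1, 0.0 if m > 0 else 1.0
    t = m / (sd / math.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), n - 1, p


def compare_calibrations(residuals: pd.DataFrame, baseline: str = "uncorrected") -> pd.DataFrame:
    """Cohort summary of residual test errors across calibration procedures.

    ``residuals`` is tidy with columns ``procedure, subject, coupling, eye,
    error_deg`` (coupling/eye optional).  Per-subject means are summarized as
    mean ± SD per (procedure, coupling, eye) cell, with a one-tailed paired
    t-test of "baseline error exceeds this procedure's error" against the
    baseline procedure, aligned by subject.
    """
    df = residuals.copy()
    for col, default in (("coupling", "all"), ("eye", "all")):
        if col not in df.columns:
            df[col] = default
    if baseline not in set(df["procedure"]):
        raise ValueError(f"baseline procedure {baseline!r} not present")
    per_subj = (
        df.groupby(["procedure", "coupling", "eye", "subject"])["error_deg"]
        .mean()
        .reset_index()
    )
    rows = []
    for (proc, coup, eye), g in per_subj.groupby(["procedure", "coupling", "eye"]):
        base = per_subj[
            (per_subj["procedure"] == baseline)
            & (per_subj["coupling"] == coup)
            & (per_subj["eye"] == eye)
        ].set_index("subject")["error_deg"]
        cur = g.set_index("subject")["error_deg"]
        if set(base.index) != set(cur.index):
            raise ValueError("subject sets are misaligned across procedures")
        cur = cur.loc[base.index]
        if proc == baseline:
            p = np.nan
        else:
            _, _, p = paired_t_one_tailed(base.to_numpy(), cur.to_numpy())
        rows.append(
            {
                "procedure": proc,
                "coupling": coup,
                "eye": eye,
                "mean_deg": float(cur.mean()),
                "sd_deg": float(cur.std(ddof=1)) if len(cur) > 1 else 0.0,
                "n_subjects": len(cur),
                "p_vs_baseline": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class QualityReport:
    """Accuracy/precision per eccentricity bin plus sampling statistics."""

    bins: pd.DataFrame           # eccentricity_deg, accuracy_median/iqr, precision_median/iqr, n
    accuracy_mean_deg: float
    accuracy_sd_deg: float
    median_isi_ms: float
    isi_iqr_ms: float
    median_rate_hz: float

    def to_dict(self) -> dict:
        return {
            "bins": self.bins.to_dict(orient="records"),
            "accuracy_mean_deg": self.accuracy_mean_deg,
            "accuracy_sd_deg": self.accuracy_sd_deg,
            "median_isi_ms": self.median_isi_ms,
            "isi_iqr_ms": self.isi_iqr_ms,
            "median_rate_hz": self.median_rate_hz,
        }


def quality_report(observations: pd.DataFrame, timestamps, geom: ScreenGeometry) -> QualityReport:
    """Assemble a quality report from a per-target observation table.

    ``observations`` needs ``target_x_deg``, ``target_y_deg``, ``error_deg``
    and optionally ``precision_deg`` columns (one row per target dwell);
    ``timestamps`` is the pooled sample-time vector for sampling statistics.
    """
    groups = bin_by_eccentricity(observations, geom)
    rows = []
    for ecc, g in groups.items():
        med, iqr, _, _ = accuracy(g["error_deg"])
        row = {"eccentricity_deg": ecc, "accuracy_median_deg": med,
               "accuracy_iqr_deg": iqr, "n": len(g)}
        if "precision_deg" in g.columns:
            pq1, pmed, pq3 = np.percentile(g["precision_deg"], [25, 50, 75])
            row["precision_median_deg"] = float(pmed)
            row["precision_iqr_deg"] = float(pq3 - pq1)
        rows.append(row)
    med_isi, isi_iqr, rate = sampling_stats(timestamps)
    err = observations["error_deg"].to_numpy(dtype=float)
    return QualityReport(
        bins=pd.DataFrame(rows),
        accuracy_mean_deg=float(err.mean()),
        accuracy_sd_deg=float(err.std(ddof=1)) if err.size > 1 else 0.0,
        median_isi_ms=med_isi,
        isi_iqr_ms=isi_iqr,
        median_rate_hz=rate,
    )
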