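"""Doubling-time estimation from plate-reader growth curves.

The estimator works on log2(OD600) versus time in minutes.  Each interior
point of each replicate gets the R-squared of the least-squares line
through the 7-point window centred on it (the point plus the three before
and after); the per-point values are averaged across replicates, and the
longest contiguous stretch with averaged R-squared >= 0.99 is the linear
(exponential-phase) range.  The least-squares slope of each replicate over
that shared window has units of doublings per minute, so the doubling time
is its reciprocal; the result is the replicate mean with its standard
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "DoublingTimeResult",
    "GrowthError",
    "windowed_r2",
    "linear_region",
    "doubling_time",
    "read_curves",
]

WINDOW_HALF = 3  # three points before and after
R2_THRESHOLD = 0.99


class GrowthError(ValueError):
    """Growth-curve analysis cannot proceed (too few points, no growth...)."""


@dataclass(frozen=True)
class GrowthCurve:
    """Replicate OD600 time series on a shared, uniformly sampled grid."""

    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray  # (replicates, n_points), positive in the analysis region

    def __post_init__(self):
        t = np.asarray(self.times, float)
        od = np.atleast_2d(np.asarray(self.od, float))
        if np.any(np.diff(t) <= 0):
            raise GrowthError("times must be strictly increasing")
        if od.shape[1] != t.size:
            raise GrowthError("OD grid does not match the time grid")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)

    @property
    def n_replicates(self) -> int:
        return self.od.shape[0]

    def log2_od(self) -> np.ndarray:
        if np.any(self.od <= 0):
            raise GrowthError("non-positive OD values cannot be log-transformed")
        return np.log2(self.od)


@dataclass(frozen=True)
class DoublingTimeResult:
    doubling_time: float  # minutes, mean over replicates
    standard_error: float  # minutes, SE over the replicate set
    linear_window: tuple[float, float]  # (t_start, t_end) minutes
    per_replicate: tuple[float, ...]


def windowed_r2(times: np.ndarray, log2_od: np.ndarray) -> np.ndarray:
    """Per-point R-squared of the 7-point window centred on each point.

    Boundary points (the first and last three) carry NaN.  A zero-variance
    window (constant signal) is assigned R-squared 0, which excludes it from
    any linear region.
    """
    t = np.asarray(times, float)
    y = np.asarray(log2_od, float)
    n = t.size
    if n < 2 * WINDOW_HALF + 1:
        raise GrowthError(f"windowed R^2 needs at least {2 * WINDOW_HALF + 1} points")
    out = np.full(n, np.nan)
    for i in range(WINDOW_HALF, n - WINDOW_HALF):
        sl = slice(i - WINDOW_HALF, i + WINDOW_HALF + 1)
        yw = y[sl]
        if np.allclose(yw, yw[0]):
            out[i] = 0.0
            continue
        r = stats.linregress(t[sl], yw).rvalue
        out[i] = r * r
    return out


def linear_region(curve: GrowthCurve, threshold: float = R2_THRESHOLD) -> tuple[float, float]:
    """Longest contiguous run where the replicate-averaged windowed
    R-squared is at or above ``threshold``; ties resolve to the earliest
    run.  Raises :class:`GrowthError` when no point qualifies."""
    y = curve.log2_od()
    r2 = np.array([windowed_r2(curve.times, row) for row in y])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN boundary columns
        avg = np.nanmean(r2, axis=0)
    ok = np.where(np.isnan(avg), False, avg >= threshold)
    best_len, best_start = 0, None
    run_start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_start is None:
        raise GrowthError(f"no stretch with averaged R^2 >= {threshold}")
    return float(curve.times[best_start]), float(curve.times[best_start + best_len - 1])


def doubling_time(curve: GrowthCurve, threshold: float = R2_THRESHOLD) -> DoublingTimeResult:
    """Doubling time (minutes) from the shared linear window.

    The same window is used for every replicate; each replicate contributes
    1/slope of its least-squares log2(OD)-vs-time fit, and the result is
    their mean with the standard error across replicates.  A non-positive
    slope (no growth in the window) is an error.
    """
    t_start, t_end = linear_region(curve, threshold)
    mask = (curve.times >= t_start) & (curve.times <= t_end)
    y = curve.log2_od()
    dts = []
    for row in y:
        slope = stats.linregress(curve.times[mask], row[mask]).slope
        if slope <= 0:
            raise GrowthError("non-positive slope in the linear window: no growth")
        dts.append(1.0 / slope)
    dts_arr = np.array(dts)
    se = (
        float(np.std(dts_arr, ddof=1) / np.sqrt(dts_arr.size))
        if dts_arr.size > 1
        else 0.0
    )
    return DoublingTimeResult(
        doubling_time=float(dts_arr.mean()),
        standard_error=se,
        linear_window=(t_start, t_end),
        per_replicate=tuple(float(x) for x in dts_arr),
    )


def read_curves(path) -> GrowthCurve:
    """Read curves from tabular CSV/TSV.

    Accepts long format (columns: time, replicate, od600) or wide format
    (first column time, one column per replicate).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if {"time", "replicate", "od600"} <= set(cols):
        wide = df.pivot(index=cols["time"], columns=cols["replicate"], values=cols["od600"])
        return GrowthCurve(wide.index.to_numpy(float), wide.to_numpy(float).T)
    times = df.iloc[:, 0].to_numpy(float)
    return GrowthCurve(times, df.iloc[:, 1:].to_numpy(float).T)
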