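"""Uniformly sampled response-quality time series.

Converts a session record into response-time (RT), RT-variability (RTV) and
catch-trial error-rate series on a shared 1-s clock, plus binary deviance
masks.  RT gaps from unanswered presentations are filled by linear
interpolation; RTV is the variance of the interpolated RT over a trailing
60-s sliding window; the error rate counts false catch-trial responses in
the same trailing window, expressed per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import SessionRecord
from .protocol import FN_CATCH, FP_CATCH

__all__ = [
    "RTSeries",
    "RTVSeries",
    "ErrorRateSeries",
    "MaskSeries",
    "make_grid",
    "extract_rt_observations",
    "interpolate_rt",
    "normalize_unit_interval",
    "sliding_rtv",
    "error_onsets",
    "error_rate_per_minute",
    "flag_increased_error_periods",
]

GRID_STEP_S = 1.0


def make_grid(duration_s: float, step_s: float = GRID_STEP_S) -> np.ndarray:
    """Uniform time grid 0..duration (inclusive of the final full step)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    return np.arange(0.0, np.floor(duration_s / step_s) * step_s + step_s / 2, step_s)


@dataclass
class RTSeries:
    """Response time on a uniform grid; ``observed`` flags grid samples that
    coincide (within half a step) with an actual button press."""

    subject_id: str
    t: np.ndarray
    values: np.ndarray
    observed: np.ndarray
    normalized: bool = False


@dataclass
class RTVSeries:
    """Sliding-window variance of RT (ms^2 raw, unit interval if normalized)."""

    subject_id: str
    t: np.ndarray
    values: np.ndarray
    window_s: float = 60.0
    normalized: bool = False


@dataclass
class ErrorRateSeries:
    """False catch-trial responses per minute (both kinds pooled), counted in
    a trailing window."""

    subject_id: str
    t: np.ndarray
    values: np.ndarray
    window_s: float = 60.0


@dataclass
class MaskSeries:
    """Boolean deviance mask on the shared grid."""

    subject_id: str
    t: np.ndarray
    mask: np.ndarray
    source: str  # "error_rate" | "rt" | "rtv"
    threshold: float


def extract_rt_observations(session: SessionRecord) -> tuple[np.ndarray, np.ndarray]:
    """(onset_s, rt_ms) pairs for every answered presentation, in onset order."""
    idx = np.flatnonzero(session.responded)
    return session.schedule.onset_s[idx], session.rt_ms[idx]


def interpolate_rt(
    onsets: np.ndarray,
    rts: np.ndarray,
    grid: np.ndarray,
    subject_id: str = "",
) -> RTSeries:
    """Linearly interpolate RT observations onto the grid.

    Piecewise linear between consecutive observations; before the first and
    after the last observation the nearest observed value is held constant.
    Raises if there are no observations at all (the series is undefined).
    """
    onsets = np.asarray(onsets, float)
    rts = np.asarray(rts, float)
    if onsets.size == 0:
        raise ValueError("cannot build an RT series from zero observations")
    values = np.interp(grid, onsets, rts)
    # a grid sample is "observed" only when a button press coincides with it
    # exactly; everywhere else the value is interpolated or held
    step = grid[1] - grid[0] if len(grid) > 1 else GRID_STEP_S
    observed = np.zeros(len(grid), bool)
    nearest = np.clip(np.round(onsets / step).astype(int), 0, len(grid) - 1)
    observed[nearest[np.abs(grid[nearest] - onsets) < 1e-9]] = True
    return RTSeries(subject_id=subject_id, t=np.asarray(grid, float), values=values, observed=observed)


def normalize_unit_interval(series):
    """Min-max normalize a series' values to [0, 1] (per subject).

    Constant series map to 0 everywhere (degenerate but defined).  Returns a
    new series of the same type with ``normalized=True`` where the type
    carries the flag.
    """
    x = series.values
    lo, hi = float(np.min(x)), float(np.max(x))
    scaled = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    kwargs = {"values": scaled}
    if hasattr(series, "normalized"):
        kwargs["normalized"] = True
    return replace(series, **kwargs)


def _trailing_window_bounds(t: np.ndarray, window_s: float) -> np.ndarray:
    """Left edge (exclusive) of the trailing window (t - w, t] per grid point,
    clipped at session start."""
    return np.maximum(t - window_s, -np.inf)


def sliding_rtv(rt: RTSeries, window_s: float = 60.0) -> RTVSeries:
    """Variance of the RT series over a trailing sliding window.

    For each grid point t the population variance (divisor n) of the RT
    samples with time in (t - window, t] is taken; samples before the session
    start simply do not exist, so early windows are partial.
    """
    t = rt.t
    span = t[-1] - t[0] if len(t) > 1 else 0.0
    if window_s > span:
        raise ValueError(f"window ({window_s}s) exceeds series span ({span}s)")
    x = rt.values.astype(float)
    # centering the whole series first keeps the cumulative-sum variance
    # numerically safe (values are O(100) ms, windows are short)
    xc = x - x.mean()
    c1 = np.concatenate(([0.0], np.cumsum(xc)))
    c2 = np.concatenate(([0.0], np.cumsum(xc * xc)))
    step = t[1] - t[0] if len(t) > 1 else GRID_STEP_S
    n_grid = len(t)
    idx = np.arange(n_grid)
    # window (t-w, t] on a uniform grid -> indices [max(0, i - w/step + 1), i]
    w_steps = int(round(window_s / step))
    lo = np.maximum(idx - w_steps + 1, 0)
    hi = idx + 1
    n = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0)
    return RTVSeries(
        subject_id=rt.subject_id, t=t, values=var, window_s=window_s,
        normalized=rt.normalized,
    )


def error_onsets(session: SessionRecord) -> np.ndarray:
    """Onset times of false catch-trial responses, both kinds pooled.

    A suprathreshold (fp_catch, 0 dB) trial is an error when it was *not*
    answered; an infrathreshold (fn_catch, 40 dB) trial is an error when it
    *was* answered.
    """
    kinds = session.schedule.kind
    missed_supra = (kinds == FP_CATCH) & ~session.responded
    answered_infra = (kinds == FN_CATCH) & session.responded
    return session.schedule.onset_s[missed_supra | answered_infra]


def error_rate_per_minute(
    session: SessionRecord,
    grid: np.ndarray,
    window_s: float = 60.0,
    subject_id: str | None = None,
) -> ErrorRateSeries:
    """Windowed catch-trial error count, expressed per minute.

    The value at t is the number of error events with onset in the trailing
    window (t - 60, t]; with the default 60-s window the count itself is the
    per-minute rate.  Early windows are partial and keep the raw count, so
    sampling the series at 60, 120, ... s partitions the session and sums to
    the total error count.
    """
    onsets = np.sort(error_onsets(session))
    grid = np.asarray(grid, float)
    # strict left edge / inclusive right edge via searchsorted sides
    hi = np.searchsorted(onsets, grid, side="right")
    lo = np.searchsorted(onsets, grid - window_s, side="right")
    counts = (hi - lo).astype(float)
    return ErrorRateSeries(
        subject_id=subject_id or session.subject_id,
        t=grid,
        values=counts * (60.0 / window_s) if window_s != 60.0 else counts,
        window_s=window_s,
    )


def flag_increased_error_periods(
    err: ErrorRateSeries, threshold_per_min: float = 2.0
) -> MaskSeries:
    """Mask of grid samples where the error rate strictly exceeds the
    threshold ("more than two errors per minute" by default)."""
    return MaskSeries(
        subject_id=err.subject_id,
        t=err.t,
        mask=err.values > threshold_per_min,
        source="error_rate",
        threshold=threshold_per_min,
    )
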