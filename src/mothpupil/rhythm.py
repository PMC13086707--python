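"""Intrinsic pupil-rhythm metrics from constant-darkness recordings.

Dark-adapted superposition eyes switch spontaneously between an open
(bright tapetal reflection) and closed state roughly every 12 hours when
kept in constant darkness after 12:12 entrainment.  This module detects
those state switches with a hysteresis crossing detector, estimates the
mean switching period, and quantifies the slow irreversible closure drift
seen in small preparations as the slope through per-cycle open-plateau
medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .curves import NormalizedCurve, _moving_average

__all__ = [
    "NotEstimableError",
    "RhythmResult",
    "detect_switches",
    "estimate_period",
    "estimate_drift",
    "analyze_rhythm",
    "RhythmAnalyzer",
]


class NotEstimableError(ValueError):
    """A rhythm quantity cannot be estimated from the available data."""


@dataclass
class RhythmResult:
    """Switch times, mean period and drift for one 36-h recording."""

    switch_times_h: list[float]
    mean_period_h: float  # nan when < 2 switches
    period_sd_h: float
    n_switches: int
    drift_slope_per_h: float  # nan when < 2 open plateaus
    state_at_start: str


def _hysteresis_switches(
    t_h: np.ndarray,
    v: np.ndarray,
    low: float,
    high: float,
    refractory_h: float,
) -> tuple[list[float], str]:
    """Core crossing detector on an already smoothed/detrended trace.

    A switch is recorded when the trace crosses from below ``low`` to above
    ``high`` (or vice versa); its time is the interpolated 0.5-crossing
    within that transition.  Consecutive switches closer than the
    refractory interval are suppressed.
    """
    if v[0] >= 0.5:
        state = "high"
        start_state = "open"
    else:
        state = "low"
        start_state = "closed"
    switches: list[float] = []
    last_extreme_idx = 0  # last sample index confirming the current state
    for i in range(len(v)):
        if state == "high":
            if v[i] >= high:
                last_extreme_idx = i
            elif v[i] < low:
                t_sw = _half_crossing(t_h, v, last_extreme_idx, i)
                if not switches or t_sw - switches[-1] >= refractory_h:
                    switches.append(t_sw)
                state = "low"
                last_extreme_idx = i
        else:
            if v[i] <= low:
                last_extreme_idx = i
            elif v[i] > high:
                t_sw = _half_crossing(t_h, v, last_extreme_idx, i)
                if not switches or t_sw - switches[-1] >= refractory_h:
                    switches.append(t_sw)
                state = "high"
                last_extreme_idx = i
    return switches, start_state


def _half_crossing(t_h: np.ndarray, v: np.ndarray, i0: int, i1: int) -> float:
    """Interpolated 0.5-crossing time within the transition window [i0, i1]."""
    for j in range(i0, i1):
        d0, d1 = v[j] - 0.5, v[j + 1] - 0.5
        if d0 == 0:
            return float(t_h[j])
        if d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            return float(t_h[j] + frac * (t_h[j + 1] - t_h[j]))
    return float(t_h[i1])


def detect_switches(
    curve: NormalizedCurve,
    low: float = 0.3,
    high: float = 0.7,
    smooth_width: int = 3,
    refractory_h: float = 2.0,
    detrend: bool = True,
) -> list[float]:
    """Hysteresis open/closed switch detection; times in hours.

    The curve is smoothed with a centred moving average (default 3 samples,
    15 min at the standard 5-min cadence).  When ``detrend`` is set and the
    drift slope is estimable from a first detection pass, the drift line is
    subtracted and detection re-run on the detrended trace.
    """
    if not 0 < low < high < 1:
        raise ValueError(f"require 0 < low < high < 1, got low={low}, high={high}")
    t_h = curve.times / 3600.0
    v = _moving_average(curve.values, smooth_width)
    switches, _ = _hysteresis_switches(t_h, v, low, high, refractory_h)
    if detrend and len(switches) >= 2:
        try:
            slope = _plateau_drift(t_h, v, switches)
        except NotEstimableError:
            return switches
        det = v - slope * (t_h - t_h[0])
        switches, _ = _hysteresis_switches(t_h, det, low, high, refractory_h)
    return switches


def estimate_period(switch_times_h: Sequence[float]) -> tuple[float, float]:
    """Mean and SD of successive switch-time differences, in hours."""
    st = np.asarray(switch_times_h, dtype=float)
    if len(st) < 2:
        raise NotEstimableError(f"period needs >= 2 switches, got {len(st)}")
    diffs = np.diff(st)
    return float(diffs.mean()), float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0


def _plateau_segments(
    t_h: np.ndarray, v: np.ndarray, switches: Sequence[float], margin_frac: float = 0.2
) -> list[tuple[float, float]]:
    """(mid-time, median value) of each open plateau between switches."""
    bounds = [t_h[0], *switches, t_h[-1]]
    plateaus = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        span = b - a
        sel = (t_h >= a + margin_frac * span) & (t_h <= b - margin_frac * span)
        if sel.sum() < 3:
            continue
        med = float(np.median(v[sel]))
        if med > 0.5:  # open state
            plateaus.append((float((a + b) / 2), med))
    return plateaus


def _plateau_drift(t_h: np.ndarray, v: np.ndarray, switches: Sequence[float]) -> float:
    plateaus = _plateau_segments(t_h, v, switches)
    if len(plateaus) < 2:
        raise NotEstimableError(
            f"drift needs >= 2 complete open plateaus, found {len(plateaus)}"
        )
    mids, meds = np.array(plateaus).T
    slope, _ = np.polyfit(mids, meds, 1)
    return float(slope)


def estimate_drift(
    curve: NormalizedCurve,
    switches: Optional[Sequence[float]] = None,
    nominal_period_h: float = 12.0,
    low: float = 0.3,
    high: float = 0.7,
) -> float:
    """Slope (per hour) of a least-squares line through open-plateau medians.

    Using per-cycle plateau medians makes the estimate robust to the rhythm
    itself.  Requires a recording span of at least two nominal periods and
    at least two complete open plateaus.
    """
    t_h = curve.times / 3600.0
    if t_h[-1] - t_h[0] < 2 * nominal_period_h:
        raise NotEstimableError(
            f"recording span {t_h[-1] - t_h[0]:.1f} h is below two nominal periods"
        )
    v = _moving_average(curve.values, 3)
    if switches is None:
        switches, _ = _hysteresis_switches(t_h, v, low, high, refractory_h=2.0)
    return _plateau_drift(t_h, v, switches)


def analyze_rhythm(
    curve: NormalizedCurve,
    low: float = 0.3,
    high: float = 0.7,
    smooth_width: int = 3,
    refractory_h: float = 2.0,
) -> RhythmResult:
    """Full rhythm summary: switches, period and drift for one recording."""
    switches = detect_switches(curve, low=low, high=high, smooth_width=smooth_width, refractory_h=refractory_h)
    t_h = curve.times / 3600.0
    v = _moving_average(curve.values, smooth_width)
    _, start_state = _hysteresis_switches(t_h, v, low, high, refractory_h)
    try:
        period, sd = estimate_period(switches)
    except NotEstimableError:
        period, sd = np.nan, np.nan
    try:
        drift = estimate_drift(curve, switches=switches, low=low, high=high)
    except NotEstimableError:
        drift = np.nan
    return RhythmResult(
        switch_times_h=list(switches),
        mean_period_h=period,
        period_sd_h=sd,
        n_switches=len(switches),
        drift_slope_per_h=drift,
        state_at_start=start_state,
    )


class RhythmAnalyzer(BaseEstimator):
    """Sklearn-style wrapper around the rhythm metrics.

    ``fit(X)`` accepts an (n_samples, 2) array of (time_s, normalised
    value) or a :class:`~mothpupil.curves.NormalizedCurve`.

    Attributes
    ----------
    switch_times_h_ : list of float
    mean_period_h_ : float
    period_sd_h_ : float
    n_switches_ : int
    drift_slope_per_h_ : float
    state_at_start_ : str
    """

    def __init__(self, low: float = 0.3, high: float = 0.7, smooth_width: int = 3, refractory_h: float = 2.0):
        self.low = low
        self.high = high
        self.smooth_width = smooth_width
        self.refractory_h = refractory_h

    def fit(self, X, y=None):
        if isinstance(X, NormalizedCurve):
            curve = X
        else:
            arr = np.asarray(X, dtype=float)
            direction = "closing" if arr[0, 1] > arr[-1, 1] else "opening"
            curve = NormalizedCurve(arr[:, 0], arr[:, 1], direction)
        result = analyze_rhythm(
            curve, low=self.low, high=self.high, smooth_width=self.smooth_width, refractory_h=self.refractory_h
        )
        self.switch_times_h_ = result.switch_times_h
        self.mean_period_h_ = result.mean_period_h
        self.period_sd_h_ = result.period_sd_h
        self.n_switches_ = result.n_switches
        self.drift_slope_per_h_ = result.drift_slope_per_h
        self.state_at_start_ = result.state_at_start
        self.result_ = result
        return self
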