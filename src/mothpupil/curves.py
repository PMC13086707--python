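"""Normalisation, bump exclusion and log-logistic kinetic fitting.

Pupil opening/closing time courses are summarised by a two-parameter
log-logistic sigmoid (the time-domain form of the classical Lipetz
response–intensity relation):

    f(t) = 1 / (1 + exp(b * (log t - log t50)))

``t50`` is the time at half brightness; ``b`` is the slope of the linear
part of the sigmoid on a log-time axis.  The adopted sign convention is
closing: b > 0 (f decreasing), opening: b < 0 (f increasing).  The model
has no offset or amplitude terms — the asymptotes are pinned at 0 and 1,
which is what fitting on min–max normalised curves assumes.

Dark re-opening recordings start with a short transient brightness "bump"
(typically within the first 5–15 min) attributed to the preceding UV
exposure; it is located and excluded before fitting, and the retained
rising limb is re-normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .imaging import ReflectanceSeries

__all__ = [
    "log_logistic",
    "NormalizedCurve",
    "BumpAnnotation",
    "LogLogisticFit",
    "normalize",
    "detect_bump",
    "trim_to_rise",
    "fit_log_logistic",
    "LogLogisticRegressor",
]

logger = logging.getLogger(__name__)

_LOGIT_3Q = 2.0 * np.log(3.0)  # logit(0.75) - logit(0.25)


def log_logistic(t, b: float, t50: float):
    """Evaluate ``1 / (1 + exp(b (log t - log t50)))`` with the t = 0 limit.

    At t = 0 the limit is 1 for b > 0 (closing starts bright) and 0 for
    b < 0 (opening starts dark).
    """
    if t50 <= 0:
        raise ValueError(f"t50 must be positive, got {t50}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.empty_like(t)
    zero = t == 0
    out[zero] = 1.0 if b > 0 else 0.0
    with np.errstate(over="ignore"):
        out[~zero] = 1.0 / (1.0 + np.exp(b * (np.log(t[~zero]) - np.log(t50))))
    return float(out[0]) if scalar else out


@dataclass
class NormalizedCurve:
    """Min–max normalised curve, times re-zeroed at analysis start."""

    times: np.ndarray
    values: np.ndarray
    direction: str  # "closing" or "opening"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.direction not in ("closing", "opening"):
            raise ValueError(f"direction must be closing|opening, got {self.direction!r}")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must start at or after 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class BumpAnnotation:
    """Location of the initial opening transient, if present."""

    present: bool
    bump_end_time_s: float  # time of the windowed minimum; 0 when absent
    bump_peak_value: float  # smoothed value at the transient peak; nan when absent


def normalize(series: ReflectanceSeries, direction: Optional[str] = None) -> NormalizedCurve:
    """Min–max rescale a gamma-corrected series to [0, 1].

    The minimum and maximum are taken over the full series.  Times are
    re-zeroed at the first sample.  When ``direction`` is omitted it is
    inferred from the overall trend (first vs last value).
    """
    if series.units != "corrected":
        raise ValueError(f"normalize expects a corrected series, got units={series.units!r}")
    if len(series) < 2:
        raise ValueError("at least two samples are required")
    v = series.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("constant series cannot be normalized (max == min)")
    if direction is None:
        direction = "closing" if v[0] > v[-1] else "opening"
    return NormalizedCurve(series.times - series.times[0], (v - vmin) / (vmax - vmin), direction)


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if width <= 1:
        return values.astype(float)
    kernel = np.ones(width)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return num / den


def detect_bump(
    curve: NormalizedCurve,
    window_s: float = 1200.0,
    smooth_width: int = 5,
    min_prominence: float = 0.05,
) -> BumpAnnotation:
    """Locate the initial transient of an opening curve.

    The curve is smoothed with a centred moving average (``smooth_width``
    samples) and the minimum of the smoothed curve within the search window
    is found.  The transient is declared present when a local maximum
    precedes that minimum by at least ``min_prominence`` (normalised
    brightness); the bump end is the time of the windowed minimum, i.e. the
    point where the sigmoid rise starts.
    """
    if curve.direction != "opening":
        raise ValueError("bump detection applies to opening curves only")
    if window_s > curve.span_s:
        raise ValueError(
            f"search window ({window_s} s) exceeds the recording span ({curve.span_s} s)"
        )
    smoothed = _moving_average(curve.values, smooth_width)
    in_window = curve.times <= curve.times[0] + window_s
    idx_min = int(np.argmin(np.where(in_window, smoothed, np.inf)))
    best_peak = np.nan
    present = False
    # the surge can already be at its peak when the recording starts, so a
    # maximum at the first sample counts; the prominence guard rejects
    # flat starts and noise wiggles
    for i in range(0, idx_min):
        left_ok = i == 0 or smoothed[i] >= smoothed[i - 1]
        if left_ok and smoothed[i] >= smoothed[i + 1]:
            if smoothed[i] - smoothed[idx_min] >= min_prominence:
                present = True
                best_peak = max(best_peak, smoothed[i]) if np.isfinite(best_peak) else smoothed[i]
    if not present:
        return BumpAnnotation(False, 0.0, np.nan)
    return BumpAnnotation(True, float(curve.times[idx_min]), float(best_peak))


def trim_to_rise(curve: NormalizedCurve, annotation: BumpAnnotation) -> NormalizedCurve:
    """Drop samples before the bump end and re-normalise the retained span.

    Times are re-zeroed at the bump end.  Without a bump the curve is
    returned re-normalised only (a no-op for already-normalised input).
    """
    if annotation.present:
        keep = curve.times >= annotation.bump_end_time_s
    else:
        keep = np.ones(len(curve), dtype=bool)
    times = curve.times[keep]
    values = curve.values[keep]
    if len(times) < 5:
        raise ValueError(f"trimming leaves only {len(times)} samples (need >= 5)")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        raise ValueError("retained span is constant; cannot re-normalize")
    return NormalizedCurve(times - times[0], (values - vmin) / (vmax - vmin), curve.direction)


@dataclass
class LogLogisticFit:
    """Fitted two-parameter log-logistic sigmoid for one curve."""

    b: float
    t50: float
    r_squared: float
    direction: str
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.t50 <= 0:
            raise ValueError("t50 must be positive")

    def __call__(self, t):
        return log_logistic(t, self.b, self.t50)

    predict = __call__


def _crossing_time(times: np.ndarray, values: np.ndarray, level: float) -> Optional[float]:
    """Linearly interpolated first crossing of ``level``, or None."""
    d = values - level
    sign_change = np.nonzero(d[:-1] * d[1:] <= 0)[0]
    for i in sign_change:
        if d[i] == d[i + 1] == 0:
            continue
        frac = d[i] / (d[i] - d[i + 1]) if d[i] != d[i + 1] else 0.0
        t = times[i] + frac * (times[i + 1] - times[i])
        if t > 0:
            return float(t)
    return None


def _initial_guess(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    t50_0 = _crossing_time(times, values, 0.5)
    t25 = _crossing_time(times, values, 0.25)
    t75 = _crossing_time(times, values, 0.75)
    if t50_0 is not None and t25 is not None and t75 is not None and t25 != t75:
        b0 = _LOGIT_3Q / (np.log(t25) - np.log(t75))
        return float(b0), t50_0
    # grid fallback when crossings are absent; the half-crossing may lie
    # outside the recorded span, so t50 candidates extend beyond it
    if t50_0 is not None:
        t50_candidates = [t50_0]
    else:
        t50_candidates = [
            float(times[0]),
            float(np.exp(np.mean(np.log(times)))),
            float(times[-1]),
            10.0 * float(times[-1]),
        ]
    b_candidates = [s * m for m in (0.5, 1.0, 2.0, 4.0, 8.0) for s in (1.0, -1.0)]
    best, best_sse = (b_candidates[0], t50_candidates[0]), np.inf
    for t50_c in t50_candidates:
        for b_c in b_candidates:
            sse = float(np.sum((values - log_logistic(times, b_c, t50_c)) ** 2))
            if sse < best_sse:
                best, best_sse = (b_c, t50_c), sse
    return float(best[0]), float(best[1])


def fit_log_logistic(
    curve: NormalizedCurve,
    zero_time_shift: float = 0.5,
) -> LogLogisticFit:
    """Least-squares fit of the two-parameter log-logistic to one curve.

    A sample at t = 0 cannot enter the log-time loss; it is shifted forward
    by ``zero_time_shift`` sample intervals (default half an interval)
    before fitting.  Optimisation runs on (b, log t50), initialised from
    interpolated quartile-crossing times, with a coarse slope grid as
    fallback.  Convergence tolerance is 1e-10 on the sum of squares within
    500 iterations; a failed fit is reported explicitly rather than raised.
    """
    times = np.asarray(curve.times, dtype=float).copy()
    values = np.asarray(curve.values, dtype=float)
    if len(times) < 5:
        raise ValueError(f"at least 5 samples are required, got {len(times)}")
    if np.all(~np.isfinite(values)):
        raise ValueError("all values are non-finite")
    if times[0] == 0:
        dt = times[1] - times[0]
        times[0] = zero_time_shift * dt

    b0, t50_0 = _initial_guess(times, values)
    log_t = np.log(times)

    def residuals(theta):
        b, log_t50 = theta
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(b * (log_t - log_t50))) - values

    result = least_squares(
        residuals,
        x0=[b0, np.log(t50_0)],
        ftol=1e-10,
        xtol=1e-12,
        max_nfev=1500,  # ~500 iterations with a 2-parameter numeric Jacobian
    )
    b, t50 = float(result.x[0]), float(np.exp(result.x[1]))
    ss_res = float(np.sum(result.fun**2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    expected_sign = 1.0 if curve.direction == "closing" else -1.0
    if b * expected_sign < 0:
        logger.warning(
            "fitted slope sign (b=%.3g) disagrees with declared direction %r", b, curve.direction
        )
    return LogLogisticFit(
        b=b,
        t50=t50,
        r_squared=r_squared,
        direction=curve.direction,
        converged=bool(result.success),
        message="" if result.success else result.message,
    )


class LogLogisticRegressor(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator for the log-logistic kinetic fit.

    ``fit(X, y)`` takes times (n_samples,) or (n_samples, 1) in seconds and
    normalised brightness values in [0, 1].

    Attributes
    ----------
    b_ : float
        Slope of the linear part of the sigmoid (log-time axis).
    t50_ : float
        Time at half brightness, seconds.
    r_squared_ : float
    direction_ : str
    converged_ : bool
    """

    def __init__(self, direction: Optional[str] = None, zero_time_shift: float = 0.5):
        self.direction = direction
        self.zero_time_shift = zero_time_shift

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        y = np.asarray(y, dtype=float)
        direction = self.direction
        if direction is None:
            direction = "closing" if y[0] > y[-1] else "opening"
        curve = NormalizedCurve(t, y, direction)
        fit = fit_log_logistic(curve, zero_time_shift=self.zero_time_shift)
        self.b_ = fit.b
        self.t50_ = fit.t50
        self.r_squared_ = fit.r_squared
        self.direction_ = fit.direction
        self.converged_ = fit.converged
        self.fit_ = fit
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return log_logistic(t, self.b_, self.t50_)
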