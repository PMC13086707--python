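"""Camera gamma-transfer calibration and inverse correction.

Consumer cameras map scene luminance to recorded grey value through a
power-law ("gamma") transfer

    Y_out = A * Y_in ** gamma

with amplitude ``A`` (grey-value units per unit luminance^gamma) and
dimensionless exponent ``gamma``.  Quantitative pupillometry needs grey
values on a luminance-linear scale, so the pipeline fits (A, gamma) from
chart calibration pairs and applies the inverse

    Y_corr = (Y_meas / A) ** (1 / gamma)

to every measured point.  The fit is ordinary nonlinear least squares in the
original response space, initialised from the exact log-log linear
regression (which already solves the noiseless case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import ReflectanceSeries

__all__ = ["CameraCalibration", "GammaTransfer", "fit_gamma", "correct"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CameraCalibration:
    """Amplitude and exponent of a camera's power-law transfer function."""

    amplitude: float
    gamma: float
    rss: Optional[float] = None  # residual sum of squares of the fit, if fitted

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    def forward(self, y_in: np.ndarray | float) -> np.ndarray | float:
        """Scene luminance -> recorded grey value."""
        return self.amplitude * np.asarray(y_in, dtype=float) ** self.gamma

    def correct(self, y_meas: np.ndarray | float) -> np.ndarray | float:
        """Recorded grey value -> luminance-linear value (inverse transfer)."""
        return (np.asarray(y_meas, dtype=float) / self.amplitude) ** (1.0 / self.gamma)


#: Identity transfer — used by the simulator when no camera effect is wanted.
IDENTITY_CAMERA = CameraCalibration(1.0, 1.0)

#: Transfer function of the NIR USB-microscope setup this pipeline targets,
#: measured by photographing a calibrated ColorChecker chart.
DEFAULT_CAMERA = CameraCalibration(16.71, 0.58)


def _gamma_model(x: np.ndarray, amplitude: float, gamma: float) -> np.ndarray:
    return amplitude * x**gamma


def fit_gamma(pairs: Sequence[tuple[float, float]] | np.ndarray) -> CameraCalibration:
    """Least-squares fit of ``Y_out = A * Y_in**gamma`` to calibration pairs.

    Parameters
    ----------
    pairs
        Sequence of (Y_in, Y_out) with Y_in the chart patch luminance in
        (0, 1] and Y_out the recorded grey value.  At least three pairs with
        strictly positive entries are required.

    Returns
    -------
    CameraCalibration with the fitted amplitude, exponent and residual sum
    of squares.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (Y_in, Y_out)")
    if len(arr) < 3:
        raise ValueError(f"at least 3 calibration pairs are required, got {len(arr)}")
    y_in, y_out = arr[:, 0], arr[:, 1]
    if np.any(y_in <= 0) or np.any(y_out <= 0):
        raise ValueError("calibration pairs must have strictly positive Y_in and Y_out")

    # log-log linear regression: exact when the pairs are noiseless
    slope, intercept = np.polyfit(np.log(y_in), np.log(y_out), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, _ = curve_fit(
            _gamma_model, y_in, y_out, p0=p0, maxfev=10_000, xtol=1e-14, ftol=1e-14
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data only
        raise RuntimeError(f"gamma-transfer fit did not converge: {exc}") from exc
    amplitude, gamma = popt
    rss = float(np.sum((y_out - _gamma_model(y_in, amplitude, gamma)) ** 2))
    return CameraCalibration(float(amplitude), float(gamma), rss=rss)


def correct(series: ReflectanceSeries, calib: CameraCalibration) -> ReflectanceSeries:
    """Apply the inverse transfer to a raw series; units become ``corrected``.

    The inverse is strictly increasing, so the ordering of values is
    preserved.  Values outside the chart's calibrated range are corrected by
    extrapolation of the power law (flagged in the log).
    """
    if series.units != "raw":
        raise ValueError(f"correct expects a raw series, got units={series.units!r}")
    if np.any(series.values < 0):
        raise ValueError("raw series contains negative values; cannot gamma-correct")
    if np.any(series.values > calib.forward(1.0)):
        logger.info("series contains values above the calibrated range; extrapolating")
    corrected = calib.correct(series.values)
    return ReflectanceSeries(series.times.copy(), np.asarray(corrected), units="corrected", truth=series.truth)


class GammaTransfer(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper for the camera transfer fit and inverse correction.

    ``fit(X, y)`` takes chart luminances ``X`` (n_samples, 1) and recorded
    grey values ``y``; ``transform`` applies the inverse transfer (grey ->
    linear) and ``inverse_transform`` the forward model.

    Attributes
    ----------
    amplitude_ : float
    gamma_ : float
    rss_ : float
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        calib = fit_gamma(np.column_stack([X, np.asarray(y, dtype=float)]))
        self.amplitude_ = calib.amplitude
        self.gamma_ = calib.gamma
        self.rss_ = calib.rss
        return self

    @property
    def calibration_(self) -> CameraCalibration:
        return CameraCalibration(self.amplitude_, self.gamma_, rss=self.rss_)

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.calibration_.correct(X)

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.calibration_.forward(X)
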