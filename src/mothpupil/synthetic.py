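"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates three recording designs used for moth
superposition-eye pupillometry under NIR illumination:

* induced closing under UV light — 1 frame/s for about 15 min, log-logistic
  decay with a brief onset delay;
* induced opening in darkness — 1 frame/min for about 90 min, an initial
  transient brightness "bump" followed by a sigmoid rise;
* intrinsic rhythm — 1 frame/5 min for 36 h in constant darkness, with
  roughly 12-hourly open/closed switching and, in small preparations, an
  irreversible linear drift toward closure.

All series pass through a gamma-nonlinear camera model with additive
Gaussian noise before being handed to the pipeline, so the inverse
correction is exercised end to end.  Every ``ReflectanceSeries`` carries a
``truth`` payload (normalised ground-truth curve, kinetic parameters,
rendered switch times) for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CameraCalibration, IDENTITY_CAMERA
from .curves import log_logistic
from .imaging import FrameStack, ReflectanceSeries

__all__ = [
    "KineticTruth",
    "BumpParams",
    "IntrinsicParams",
    "NoiseModel",
    "EyeGeometry",
    "generate_calibration_pairs",
    "simulate_induced_series",
    "simulate_intrinsic_series",
    "render_frames",
    "generate_specimen_records",
]


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth log-logistic parameters for an induced response."""

    b: float  # > 0 closing, < 0 opening
    t50_s: float

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("slope b must be nonzero")
        if self.t50_s <= 0:
            raise ValueError(f"t50 must be positive, got {self.t50_s}")

    @property
    def direction(self) -> str:
        return "closing" if self.b > 0 else "opening"


@dataclass(frozen=True)
class BumpParams:
    """Additive transient pulse at the start of a dark re-opening series.

    The surge when the UV stimulus switches off is effectively
    instantaneous at the recording timescale, so the pulse is already at
    ``peak_height`` when the recording starts, holds until ``peak_time_s``,
    and then decays exponentially with time constant ``decay_tau_s`` — the
    simplest shape producing a sudden brightness increase that quickly
    falls to a minimum before the sigmoid rise takes over.
    """

    peak_height: float
    peak_time_s: float
    decay_tau_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.peak_height <= 1:
            raise ValueError("peak_height must lie in [0, 1]")
        if self.peak_time_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("peak_time_s and decay_tau_s must be positive")

    def pulse(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        decaying = self.peak_height * np.exp(-(t - self.peak_time_s) / self.decay_tau_s)
        return np.where(t <= self.peak_time_s, self.peak_height, decaying)


@dataclass(frozen=True)
class IntrinsicParams:
    """Constant-darkness rhythm: alternating open/closed plateaus.

    Transitions between plateaus use the same log-logistic family as the
    induced kinetics, with slope ``transition_b`` and a half-crossing at the
    stored switch time (transition onset ``transition_lead_h`` hours
    before).  ``drift_per_h`` adds a linear trend in normalised brightness
    (negative for the irreversible closure seen in small species).
    """

    period_h: float = 12.0
    transition_b: float = 6.0
    drift_per_h: float = 0.0
    phase_offset_h: float = 0.0
    transition_lead_h: float = 0.5
    state_at_start: str = "open"

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError(f"period_h must be positive, got {self.period_h}")
        if self.transition_b <= 0:
            raise ValueError("transition_b must be positive")
        if self.transition_lead_h <= 0:
            raise ValueError("transition_lead_h must be positive")
        if self.state_at_start not in ("open", "closed"):
            raise ValueError("state_at_start must be open|closed")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise in normalised-brightness units."""

    sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


NO_NOISE = NoiseModel(sigma=0.0, seed=0)


def _apply_camera(
    g: np.ndarray, calib: CameraCalibration, noise: Optional[NoiseModel]
) -> np.ndarray:
    """Forward camera model with noise added after the nonlinearity.

    Noise sigma is expressed in normalised (pre-amplitude) units:
    Y = A * (g**gamma + sigma * eps), floored at 0.
    """
    compressed = np.clip(g, 0.0, 1.0) ** calib.gamma
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        compressed = compressed + noise.sigma * rng.standard_normal(len(compressed))
    return np.clip(calib.amplitude * compressed, 0.0, None)


def generate_calibration_pairs(
    calib: CameraCalibration,
    luminances: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Chart calibration pairs: Y_out = A * Y_in**gamma + N(0, sigma).

    Returns an (n, 2) array of (Y_in, Y_out).  Luminances must be strictly
    positive (chart patches are reflective, never perfectly black).
    """
    y_in = np.asarray(luminances, dtype=float)
    if y_in.size == 0:
        raise ValueError("luminances must be nonempty")
    if np.any(y_in <= 0):
        raise ValueError("luminances must be strictly positive")
    y_out = np.asarray(calib.forward(y_in), dtype=float)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y_out = y_out + sigma * rng.standard_normal(y_in.shape)
    return np.column_stack([y_in, y_out])


def simulate_induced_series(
    truth: KineticTruth,
    duration_s: float,
    dt_s: float,
    bump: Optional[BumpParams] = None,
    calib: CameraCalibration = IDENTITY_CAMERA,
    noise: Optional[NoiseModel] = None,
) -> ReflectanceSeries:
    """Simulate a UV-induced closing or dark-opening recording.

    The normalised ground truth is the log-logistic ``f(t; b, t50)`` plus
    the optional bump pulse, clipped to [0, 1], then passed through the
    camera forward model with additive noise.  The payload stores the
    noiseless normalised curve for recovery tests.
    """
    if dt_s <= 0 or duration_s <= dt_s:
        raise ValueError("require duration_s > dt_s > 0")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    g = log_logistic(t, truth.b, truth.t50_s)
    if bump is not None:
        g = g + bump.pulse(t)
    g = np.clip(g, 0.0, 1.0)
    values = _apply_camera(g, calib, noise)
    return ReflectanceSeries(
        t,
        values,
        units="raw",
        truth={"g": g, "kinetics": truth, "bump": bump, "direction": truth.direction},
    )


def _intrinsic_truth_curve(params: IntrinsicParams, t_h: np.ndarray) -> tuple[np.ndarray, list[float]]:
    duration_h = float(t_h[-1])
    switch_times = []
    k = 1
    while params.phase_offset_h + k * params.period_h <= duration_h + 1e-9:
        tau = params.phase_offset_h + k * params.period_h
        if tau > 0:
            switch_times.append(tau)
        k += 1
    g = np.full_like(t_h, 1.0 if params.state_at_start == "open" else 0.0)
    sign = -1.0 if params.state_at_start == "open" else 1.0
    lead = params.transition_lead_h
    for tau in switch_times:
        u = t_h - (tau - lead)
        step = np.zeros_like(t_h)
        pos = u > 0
        # log-logistic smooth step: half-crossing at tau, onset at tau - lead
        step[pos] = 1.0 / (1.0 + np.exp(-params.transition_b * (np.log(u[pos]) - np.log(lead))))
        g = g + sign * step
        sign = -sign
    g = np.clip(g + params.drift_per_h * t_h, 0.0, 1.0)
    return g, switch_times


def simulate_intrinsic_series(
    params: IntrinsicParams,
    duration_h: float = 36.0,
    dt_min: float = 5.0,
    calib: CameraCalibration = IDENTITY_CAMERA,
    noise: Optional[NoiseModel] = None,
) -> ReflectanceSeries:
    """Simulate a constant-darkness recording with open/closed switching.

    Switch times are at ``phase_offset_h + k * period_h`` for k = 1, 2, ...
    up to the recording end, and are stored in the truth payload exactly as
    rendered.  Times in the returned series are in seconds.
    """
    if duration_h <= 0 or dt_min <= 0:
        raise ValueError("require duration_h > 0 and dt_min > 0")
    t_h = np.arange(0.0, duration_h + dt_min / 120.0, dt_min / 60.0)
    g, switch_times = _intrinsic_truth_curve(params, t_h)
    values = _apply_camera(g, calib, noise)
    return ReflectanceSeries(
        t_h * 3600.0,
        values,
        units="raw",
        truth={
            "g": g,
            "params": params,
            "switch_times_h": switch_times,
            "state_at_start": params.state_at_start,
        },
    )


@dataclass(frozen=True)
class EyeGeometry:
    """Disc geometry for rendered frames (pixels; image is square)."""

    image_size: int = 64
    eye_radius: float = 24.0
    pupil_radius: float = 10.0
    eye_grey: float = 40.0
    background_grey: float = 8.0
    background_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.pupil_radius < self.eye_radius < self.image_size / 2):
            raise ValueError(
                "require pupil_radius < eye_radius < image_size / 2, got "
                f"{self.pupil_radius}, {self.eye_radius}, {self.image_size / 2}"
            )


def render_frames(
    series: ReflectanceSeries,
    geometry: EyeGeometry = EyeGeometry(),
    seed: int = 0,
) -> FrameStack:
    """Render a series as 8-bit frames: background, dim eye disc, pupil disc.

    The pupil disc's grey level equals the series value at that time,
    clipped to [0, 255] and quantised to 8 bits.  Disc membership uses the
    pixel-centre-within-radius rule, matching the imaging module.
    """
    n = len(series)
    size = geometry.image_size
    centre = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    r2 = (xx - centre) ** 2 + (yy - centre) ** 2
    eye_mask = r2 <= geometry.eye_radius**2
    pupil_mask = r2 <= geometry.pupil_radius**2
    rng = np.random.default_rng(seed)
    frames = np.empty((n, size, size), dtype=np.uint8)
    for i, v in enumerate(series.values):
        frame = np.full((size, size), geometry.background_grey, dtype=float)
        if geometry.background_sigma > 0:
            frame += geometry.background_sigma * rng.standard_normal((size, size))
        frame[eye_mask] = geometry.eye_grey
        frame[pupil_mask] = v
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return FrameStack(frames, series.times.copy())


_SPECIES = ("CP", "LB", "GM")
_SEXES = ("male", "female")
_TEMPERATURES = (15.0, 22.0)


def generate_specimen_records(
    n_per_cell: int = 10,
    b_effects: Optional[Mapping[str, Mapping[object, float]]] = None,
    t50_effects: Optional[Mapping[str, Mapping[object, float]]] = None,
    baseline_b: float = 2.5,
    baseline_t50_s: float = 300.0,
    sigma_b: float = 1.0,
    sigma_log_t50: float = 0.2,
    phase: str = "closing",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-specimen kinetic-parameter table for the stats module.

    One row per specimen in a full species x sex x temperature factorial.
    ``b_effects`` / ``t50_effects`` map factor name -> {level: shift}; b
    shifts are additive in slope units, t50 shifts are additive on log(t50).
    Residual noise is Gaussian (``sigma_b`` on b, ``sigma_log_t50`` on
    log t50).  With no effects the table is a pure-noise null.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for sp in _SPECIES:
        for sex in _SEXES:
            for temp in _TEMPERATURES:
                shift_b = _lookup(b_effects, sp, sex, temp)
                shift_t = _lookup(t50_effects, sp, sex, temp)
                for _ in range(n_per_cell):
                    b = baseline_b + shift_b + sigma_b * rng.standard_normal()
                    log_t50 = np.log(baseline_t50_s) + shift_t + sigma_log_t50 * rng.standard_normal()
                    rows.append(
                        {
                            "specimen_id": f"sim{idx:04d}",
                            "species": sp,
                            "sex": sex,
                            "temperature_C": temp,
                            "phase": phase,
                            "b": b,
                            "t50_s": float(np.exp(log_t50)),
                        }
                    )
                    idx += 1
    return pd.DataFrame(rows)


def _lookup(
    effects: Optional[Mapping[str, Mapping[object, float]]], sp: str, sex: str, temp: float
) -> float:
    if not effects:
        return 0.0
    total = 0.0
    level = {"species": sp, "sex": sex, "temperature_C": temp}
    for factor, shifts in effects.items():
        if factor not in level:
            raise ValueError(f"unknown factor {factor!r}")
        total += float(shifts.get(level[factor], 0.0))
    return total
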