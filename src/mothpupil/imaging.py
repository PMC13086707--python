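"""Extraction of the reflected-light proxy from NIR eye-image stacks.

The measured quantity per frame is the *integrated density* over a circular
region of interest (ROI): ROI area multiplied by the mean grey value within
it, which equals the plain sum of member-pixel grey values when the area is
taken as the member-pixel count.  Pixel membership uses the pixel-centre
convention: a pixel belongs to the ROI when the Euclidean distance from its
centre (integer coordinates, x = column, y = row) to the ROI centre is at
most the radius.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CircularROI",
    "FrameStack",
    "ReflectanceSeries",
    "integrated_density",
    "extract_series",
]


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest, pixel-centre convention, 0-based."""

    centre_x: float
    centre_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask for a frame of the given (rows, cols) shape."""
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (xx - self.centre_x) ** 2 + (yy - self.centre_y) ** 2 <= self.radius**2

    def check_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if (
            self.centre_x - self.radius < 0
            or self.centre_y - self.radius < 0
            or self.centre_x + self.radius > w - 1
            or self.centre_y + self.radius > h - 1
        ):
            raise ValueError(
                f"ROI (cx={self.centre_x}, cy={self.centre_y}, r={self.radius}) "
                f"extends outside frame bounds {w}x{h} (pixel-centre convention)"
            )


@dataclass
class FrameStack:
    """Ordered grayscale frames with strictly increasing per-frame timestamps."""

    frames: np.ndarray  # (n, rows, cols)
    timestamps: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame is required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    # ---- I/O -------------------------------------------------------------

    def to_tiff(self, path: str | Path, timestamps_csv: str | Path | None = None) -> None:
        """Write a multi-page TIFF plus a sidecar CSV with the timestamps."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.frames, photometric="minisblack")
        sidecar = Path(timestamps_csv) if timestamps_csv else path.with_suffix(".timestamps.csv")
        with open(sidecar, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "time_s"])
            for i, t in enumerate(self.timestamps):
                writer.writerow([i, repr(float(t))])

    @classmethod
    def from_tiff(cls, path: str | Path, timestamps_csv: str | Path | None = None) -> "FrameStack":
        import tifffile

        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = Path(timestamps_csv) if timestamps_csv else path.with_suffix(".timestamps.csv")
        if sidecar.exists():
            ts = _read_timestamp_csv(sidecar)
        else:
            ts = np.arange(len(frames), dtype=float)
        return cls(frames, ts)

    @classmethod
    def from_png_dir(cls, directory: str | Path, timestamps: Optional[Sequence[float]] = None) -> "FrameStack":
        """Read frames from a directory of PNGs, sorted by filename."""
        import imageio.v3 as iio

        paths = sorted(Path(directory).glob("*.png"))
        if not paths:
            raise ValueError(f"no PNG files found in {directory}")
        frames = np.stack([iio.imread(p) for p in paths])
        if frames.ndim == 4:  # RGB(A) -> luminance by channel mean
            frames = frames[..., :3].mean(axis=-1)
        ts = np.asarray(timestamps, dtype=float) if timestamps is not None else np.arange(len(frames), dtype=float)
        return cls(frames, ts)


def _read_timestamp_csv(path: Path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return np.array([float(r["time_s"]) for r in rows])


@dataclass
class ReflectanceSeries:
    """Timestamped eye-brightness values for one specimen and phase.

    ``units`` tracks the pipeline stage: ``raw`` (integrated density or the
    simulator's camera output), ``corrected`` (gamma-linearised) or
    ``normalized``.  ``truth`` optionally carries the simulator's ground
    truth so recovery tests can compare against it.
    """

    times: np.ndarray
    values: np.ndarray
    units: str = "raw"
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.units not in ("raw", "corrected", "normalized"):
            raise ValueError(f"unknown units flag {self.units!r}")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "raw") -> "ReflectanceSeries":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["value"].to_numpy(), units=units)


def integrated_density(frame: np.ndarray, roi: CircularROI) -> float:
    """ROI area times mean grey value = sum of member-pixel grey values.

    Raises ``ValueError`` when the ROI is not fully inside the frame.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D grayscale")
    roi.check_inside(frame.shape)
    mask = roi.mask(frame.shape)
    return float(frame[mask].sum(dtype=np.float64))


def extract_series(stack: FrameStack, roi: CircularROI) -> ReflectanceSeries:
    """One integrated-density value per frame; timestamps carried through."""
    if len(stack) == 0:
        raise ValueError("cannot extract a series from an empty stack")
    roi.check_inside(stack.frame_shape)
    mask = roi.mask(stack.frame_shape)
    values = stack.frames[:, mask].sum(axis=1, dtype=np.float64)
    return ReflectanceSeries(stack.timestamps.copy(), values, units="raw")
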