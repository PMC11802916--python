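"""Core calibrated containers shared across the pipeline.

Conventions
-----------
Images use the row/column convention with the origin at the top-left pixel;
``x`` runs along columns and ``y`` along rows, both in µm (``pixel *
pixel_size``). Velocities are reported in µm/min. Exported angles are
measured counter-clockwise from +x after flipping the y axis, so a vector
pointing "up" in the displayed image has a +90° angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Movie",
    "MaskSeries",
    "FlowField",
    "ScalarField",
    "Track",
    "FRAPSeries",
    "GroundTruth",
]


class ParameterizationError(ValueError):
    """Raised when inputs violate an operation's stated preconditions."""


class UndefinedResultError(ValueError):
    """Raised when a quantity is undefined for the given data (e.g. empty region)."""


@dataclass
class Movie:
    """Calibrated image sequence.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` for a single channel or ``(T, C, H, W)``
        for multiple channels.
    channels
        Channel names; length must match the channel axis (a single-channel
        movie may use a one-element list).
    pixel_size
        µm per pixel.
    frame_interval
        Seconds between consecutive frames.
    """

    frames: np.ndarray
    channels: list[str]
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.pixel_size <= 0:
            raise ParameterizationError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ParameterizationError("frame_interval must be > 0")
        if self.frames.ndim == 3:
            if len(self.channels) != 1:
                raise ParameterizationError(
                    "3D frame array implies a single channel"
                )
        elif self.frames.ndim == 4:
            if self.frames.shape[1] != len(self.channels):
                raise ParameterizationError(
                    "channel axis length does not match channel names"
                )
        else:
            raise ParameterizationError("frames must be (T,H,W) or (T,C,H,W)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[-2:]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(T, H, W)`` stack for one named channel."""
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in {self.channels}")
        if self.frames.ndim == 3:
            return self.frames
        return self.frames[:, self.channels.index(name)]


@dataclass
class MaskSeries:
    """Per-frame binary masks aligned with a movie."""

    masks: np.ndarray  # (T, H, W) bool
    pixel_size: float
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise ParameterizationError("masks must be (T,H,W)")
        if self.pixel_size <= 0:
            raise ParameterizationError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class FlowField:
    """Per-frame vector field on a regular grid.

    ``u``/``v`` are the x/y velocity components in µm/min with shape
    ``(T, ny, nx)``; ``x``/``y`` give node coordinates in µm; ``valid`` flags
    nodes carrying a measurement. ``corr`` optionally stores the peak
    correlation score per node.
    """

    x: np.ndarray  # (nx,) µm
    y: np.ndarray  # (ny,) µm
    u: np.ndarray  # (T, ny, nx) µm/min
    v: np.ndarray  # (T, ny, nx) µm/min
    valid: np.ndarray  # (T, ny, nx) bool
    grid_spacing: float  # µm
    frame_interval: float  # s
    corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.u.shape != self.v.shape or self.u.shape != self.valid.shape:
            raise ParameterizationError("u, v and valid must share shape")
        if self.grid_spacing <= 0:
            raise ParameterizationError("grid_spacing must be > 0")
        if not np.all(np.isfinite(self.u[self.valid])) or not np.all(
            np.isfinite(self.v[self.valid])
        ):
            raise ParameterizationError("valid nodes must carry finite velocities")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    def speed(self) -> np.ndarray:
        """Per-node speed magnitude, µm/min (NaN where invalid)."""
        s = np.hypot(self.u, self.v)
        return np.where(self.valid, s, np.nan)


@dataclass
class ScalarField:
    """Per-frame scalar map on a regular grid (divergence, deformation, ratio)."""

    x: np.ndarray  # (nx,) µm
    y: np.ndarray  # (ny,) µm
    values: np.ndarray  # (T, ny, nx)
    valid: np.ndarray  # (T, ny, nx) bool
    units: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.ndim == 2:
            self.valid = self.valid[None]
        if self.values.shape != self.valid.shape:
            raise ParameterizationError("values and valid must share shape")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ParameterizationError("valid entries must be finite")


@dataclass
class Track:
    """Time-stamped centroid positions of one tracked object (µm)."""

    t: np.ndarray  # (n,) seconds
    x: np.ndarray  # (n,) µm
    y: np.ndarray  # (n,) µm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 2:
            raise ParameterizationError("a track needs at least 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ParameterizationError("track times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.t.size

    def positions(self) -> np.ndarray:
        """``(n, 2)`` array of (x, y) positions in µm."""
        return np.column_stack([self.x, self.y])

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class FRAPSeries:
    """Three-ROI FRAP intensity traces.

    ``time_s`` is 0 at the first post-bleach frame (pre-bleach frames have
    negative times). The pre-bleach signal of each ROI is the mean of the
    first ``n_pre`` frames. Default ROI geometry mirrors typical lamellar
    FRAP acquisition: 70×70 px bleach/control ROIs, 20×20 px background ROI,
    16 px bleach-spot diameter.
    """

    time_s: np.ndarray
    bleach: np.ndarray
    control: np.ndarray
    background: np.ndarray
    n_pre: int = 5
    roi_geometry: Mapping[str, float] = field(
        default_factory=lambda: {
            "bleach_px": 70,
            "control_px": 70,
            "background_px": 20,
            "spot_diameter_px": 16,
        }
    )

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bleach = np.asarray(self.bleach, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.time_s.size
        if not (self.bleach.size == self.control.size == self.background.size == n):
            raise ParameterizationError("all traces must share length")
        if self.n_pre < 1 or self.n_pre >= n:
            raise ParameterizationError("n_pre must be in [1, n_frames)")
        if self.pre_bleach_mean("control") <= float(np.mean(self.background)):
            raise ParameterizationError(
                "pre-bleach control signal must exceed the background mean"
            )

    def pre_bleach_mean(self, roi: str) -> float:
        trace = {"bleach": self.bleach, "control": self.control,
                 "background": self.background}[roi]
        return float(np.mean(trace[: self.n_pre]))

    @property
    def t0_index(self) -> int:
        """Index of the first post-bleach frame (time 0)."""
        return int(np.argmin(np.abs(self.time_s)))


@dataclass
class GroundTruth:
    """Known generative parameters attached to every synthetic dataset."""

    kind: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        for k, val in self.params.items():
            val = float(val)
            if not np.isfinite(val):
                raise ParameterizationError(f"ground-truth param {k} is not finite")
            self.params[k] = val
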