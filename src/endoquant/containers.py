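"""Calibrated raster containers and lightweight record types.

All spatial quantities are in micrometres.  Pixel centres sit at
half-integer multiples of the pixel pitch, with the origin at the image
top-left corner: pixel ``(row j, col i)`` has its centre at
``x = (i + 0.5) * pixel_size_um``, ``y = (j + 0.5) * pixel_size_um``.
Z-stacks are ordered basal (plane 0) to apical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImagePlane",
    "MultiChannelImage",
    "ZStack",
    "TimeSeries",
    "Spot",
    "LineProfile",
    "Trajectory",
]


@dataclass
class ImagePlane:
    """A single calibrated 2-D intensity raster (photon counts)."""

    data: np.ndarray  # (rows, cols)
    pixel_size_um: float = 0.1
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("ImagePlane requires a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometres."""
        return (
            self.data.shape[1] * self.pixel_size_um,
            self.data.shape[0] * self.pixel_size_um,
        )


class _ChannelContainer:
    """Shared behaviour for containers holding one array per channel."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def _check_channels(self, expected_ndim: int) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        for arr in self.channels.values():
            if arr.ndim != expected_ndim:
                raise ValueError(f"channel arrays must be {expected_ndim}-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"no channel {channel!r}")
        return self.channels[channel]


@dataclass
class MultiChannelImage(_ChannelContainer):
    """Several co-registered 2-D channels of one field of view."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self._check_channels(2)

    def plane(self, channel: str) -> ImagePlane:
        return ImagePlane(self[channel], self.pixel_size_um, channel)


@dataclass
class ZStack(_ChannelContainer):
    """Per-channel (z, rows, cols) stacks; plane 0 is the basal section."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.1
    z_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self._check_channels(3)
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be positive")

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def plane(self, channel: str, z: int) -> ImagePlane:
        return ImagePlane(self[channel][z], self.pixel_size_um, channel)


@dataclass
class TimeSeries(_ChannelContainer):
    """Per-channel (t, rows, cols) movies."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.05

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self._check_channels(3)
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def plane(self, channel: str, frame: int) -> ImagePlane:
        return ImagePlane(self[channel][frame], self.pixel_size_um, channel)


@dataclass
class Spot:
    """A diffraction-limited fluorescence cluster with sub-pixel position."""

    x_um: float
    y_um: float
    photons: float
    channel: str = ""
    z_plane: Optional[int] = None
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.photons < 0:
            raise ValueError("photons must be non-negative")


@dataclass
class LineProfile:
    """Intensity samples along a segment crossing a cell boundary.

    Samples are ordered from outside the cell towards the inside; positions
    are distances (um) from the first sample and strictly increase.
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    outside_to_inside: bool = True

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.shape != self.intensities.shape:
            raise ValueError("positions and intensities must match in length")
        if self.positions_um.size < 5:
            raise ValueError("a profile needs at least 5 samples")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return self.positions_um.size

    def reversed(self) -> "LineProfile":
        p = self.positions_um
        return LineProfile(
            p[-1] - p[::-1],
            self.intensities[::-1].copy(),
            not self.outside_to_inside,
        )


@dataclass
class Trajectory:
    """Time-ordered positions of one linked particle.

    Frames are consecutive integers (no gaps: a missed link terminates a
    trajectory and starts a new one).
    """

    id: int
    channel: str
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    x_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    photons: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.photons = np.asarray(self.photons, dtype=float)
        n = self.frames.size
        if not (self.x_um.size == self.y_um.size == n):
            raise ValueError("frames, x_um, y_um must have equal length")
        if self.photons.size == 0:
            self.photons = np.zeros(n)
        if n > 1 and np.any(np.diff(self.frames) != 1):
            raise ValueError("trajectory frames must be consecutive")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in um."""
        return np.column_stack([self.x_um, self.y_um])

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x_um), np.diff(self.y_um))
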