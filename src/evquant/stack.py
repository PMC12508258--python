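"""Multi-channel, multi-timepoint image container.

The canonical in-memory layout is a float32 array with axes (time, channel,
y, x) plus the acquisition metadata needed by the quantification stages:
pixel size (nm), per-channel exposure (ms) and timepoints (minutes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Per-channel, per-timepoint 2D intensity grids with acquisition metadata.

    Parameters
    ----------
    data
        Array of shape ``(T, C, Y, X)``; lower-dimensional arrays are
        promoted (2D -> one timepoint, one channel; 3D -> one timepoint).
    channel_names
        One name per channel (fluorophore or marker label).
    timepoints_min
        Acquisition time of each frame, minutes, ascending, first 0.
    pixel_size_nm
        Lateral pixel size in nm.
    exposure_ms
        Exposure per channel in ms (scalar broadcast to all channels).
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = ("ch0",)
    timepoints_min: tuple[float, ...] = (0.0,)
    pixel_size_nm: float = 65.0
    exposure_ms: tuple[float, ...] = (100.0,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"image data must be 2D-4D, got {arr.ndim}D")
        self.data = arr
        t, c = arr.shape[:2]
        if len(self.channel_names) != c:
            if len(self.channel_names) == 1 and c > 1:
                self.channel_names = tuple(f"ch{i}" for i in range(c))
            else:
                raise ValueError("channel_names length does not match data")
        if len(self.timepoints_min) != t:
            raise ValueError("timepoints_min length does not match data")
        exp = self.exposure_ms
        if np.isscalar(exp):
            exp = (float(exp),) * c
        if len(exp) == 1 and c > 1:
            exp = tuple(exp) * c
        if len(exp) != c:
            raise ValueError("exposure_ms length does not match channels")
        self.exposure_ms = tuple(float(e) for e in exp)
        self.channel_names = tuple(self.channel_names)
        self.timepoints_min = tuple(float(t_) for t_ in self.timepoints_min)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None

    def frame(self, t: int = 0, channel: int | str = 0) -> np.ndarray:
        """Return one 2D frame (a view)."""
        if isinstance(channel, str):
            channel = self.channel_index(channel)
        return self.data[t, channel]

    def replace(self, **kw) -> "ImageStack":
        return dataclasses.replace(self, **kw)
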