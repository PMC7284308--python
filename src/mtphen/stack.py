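"""Calibrated multichannel image stacks.

The in-memory container for confocal data is a plain numpy array with axis
order ``(channel, z, y, x)`` plus the two calibration scalars every
downstream measurement needs: the lateral pixel size (μm/px) and the axial
step between optical sections (μm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A multichannel 3D voxel grid with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_z, n_y, n_x)``.
    um_per_px:
        Lateral calibration, micrometres per pixel (x and y).
    z_step_um:
        Axial distance between consecutive slices, micrometres.
    channel_names:
        One lowercase name per channel (e.g. ``("dapi", "tnni", ...)``).
    """

    data: np.ndarray
    um_per_px: float
    z_step_um: float
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4D (channel, z, y, x), got {self.data.ndim}D"
            )
        if self.um_per_px <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration must be positive")
        if self.channel_names and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        return self.data[self.channel_index(which)]

    def channel_index(self, which: int | str) -> int:
        if isinstance(which, str):
            try:
                return self.channel_names.index(which.lower())
            except ValueError:
                raise KeyError(
                    f"channel {which!r} not in {self.channel_names}"
                ) from None
        idx = int(which)
        if not 0 <= idx < self.n_channels:
            raise KeyError(f"channel index {idx} out of range")
        return idx
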