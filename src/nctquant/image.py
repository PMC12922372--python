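"""Core image container.

Every metric in this package consumes a :class:`ChannelImage`: one 2-D
intensity grid for one fluorescence channel, together with the physical
pixel size in micrometres per pixel. Pixel indexing is 0-based, row-major,
with pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelImage", "um_to_px"]


def um_to_px(length_um: float, pixel_size: float) -> int:
    """Convert a physical length to pixels, rounding half up.

    Round-half-up (not banker's rounding) so that e.g. 0.5 px maps to 1 px;
    this is the single µm→px convention used throughout the package.
    """
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    return int(np.floor(length_um / pixel_size + 0.5))


@dataclass
class ChannelImage:
    """A single-channel 2-D image with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite intensities. Stored as float64.
    pixel_size
        Physical size of one pixel in µm/px; must be > 0.
    channel_name
        Label for the channel (e.g. ``"DAPI"``, ``"RanGAP1"``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = field(default="")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("pixels contain negative intensities")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0 µm/px, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size**2
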