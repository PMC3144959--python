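"""Core section-image container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError

__all__ = ["ColorSlice"]


@dataclass
class ColorSlice:
    """One 2D RGB histology section.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
    order_index : position in the ventral-to-dorsal series
    section_thickness_um : nominal physical thickness of the section
    """

    pixels: np.ndarray
    order_index: int = 0
    section_thickness_um: float = 20.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError("ColorSlice.pixels must be an (H, W, 3) array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("ColorSlice.pixels must be non-empty")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]
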