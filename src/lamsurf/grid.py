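"""Visual-field pixel grids.

A single square grid convention is shared by the stimulus renderer, the pRF
forward model and the visual-field projection: x increases rightward, y
upward, origin at fixation, units are degrees of visual angle, and angles are
measured counter-clockwise from the positive x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square pixel grid over the visual field, centred on fixation.

    Parameters
    ----------
    extent_deg
        Full width/height of the grid in degrees of visual angle.
    deg_per_pixel
        Degrees of visual angle per pixel.
    """

    extent_deg: float
    deg_per_pixel: float

    def __post_init__(self) -> None:
        if self.extent_deg <= 0 or self.deg_per_pixel <= 0:
            raise ValueError("extent_deg and deg_per_pixel must be positive")

    @property
    def n_pixels(self) -> int:
        # odd pixel count so that one pixel centre sits exactly on fixation
        n = int(round(self.extent_deg / self.deg_per_pixel))
        return n if n % 2 == 1 else n + 1

    @property
    def coords(self) -> np.ndarray:
        """Pixel-centre coordinates along one axis (deg), ascending."""
        n = self.n_pixels
        return (np.arange(n) - (n - 1) / 2) * self.deg_per_pixel

    @property
    def centre_px(self) -> tuple[int, int]:
        """(x, y) pixel index of fixation."""
        c = (self.n_pixels - 1) // 2
        return (c, c)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of pixel-centre coordinates in degrees.

        Row index increases with y so that ``frames[:, iy, ix]`` addresses the
        pixel at ``(coords[ix], coords[iy])``.
        """
        c = self.coords
        return np.meshgrid(c, c, indexing="xy")

    def to_dict(self) -> dict:
        return {"extent_deg": self.extent_deg, "deg_per_pixel": self.deg_per_pixel}

    @classmethod
    def from_dict(cls, d: dict) -> "VisualFieldGrid":
        return cls(extent_deg=float(d["extent_deg"]), deg_per_pixel=float(d["deg_per_pixel"]))
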