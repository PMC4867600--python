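"""Shared raster/physical coordinate conventions.

Physical coordinates: x grows to the viewer's right, y grows upward.
The ventral (anterior) side of the thorax is at large y, the dorsal
(posterior) side at small y.  Rasters follow the usual image layout:
row 0 is the ventral-most row, the last row is dorsal-most.  Columns
use the radiological convention by default: the viewer's left (column 0)
is the patient's right side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RasterExtent:
    """Mapping between pixel indices of an M x N raster and physical coordinates.

    Pixel (m, n) covers a rectangle of size (dy, dx); its center is returned by
    :meth:`pixel_centers`.  Row 0 maps to the top of the extent (y_max, ventral).
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    shape: tuple[int, int]  # (M rows, N cols)

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.shape[1]

    @property
    def dy(self) -> float:
        return (self.y_max - self.y_min) / self.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (M, N) with the physical pixel centers."""
        M, N = self.shape
        x = self.x_min + (np.arange(N) + 0.5) * self.dx
        y = self.y_max - (np.arange(M) + 0.5) * self.dy
        return np.meshgrid(x, y)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )


def polygon_area(points: np.ndarray) -> float:
    """Signed area of a closed polygon (positive = counter-clockwise)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
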