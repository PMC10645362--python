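"""Shared in-memory containers for plate scans and colony grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlateImage:
    """An 8-bit RGB scan of a pinned colony array (or a disc-diffusion plate).

    ``pixels`` is a height x width x 3 uint8 array. ``grid_rows`` /
    ``grid_cols`` give the expected pinning density (32 x 48 for a
    1536-density array); they are 1 x 1 for disc images. ``px_per_cm`` is
    optional scanner resolution used only to report distances in cm.
    """

    pixels: np.ndarray
    plate_id: str = "plate"
    condition: str = "vehicle"
    replicate_id: str = "rep1"
    grid_rows: int = 32
    grid_cols: int = 48
    px_per_cm: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = np.round(px).astype(np.uint8)
        self.pixels = px
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must contain at least one position")

    @property
    def red(self) -> np.ndarray:
        return self.pixels[..., 0].astype(float)

    @property
    def green(self) -> np.ndarray:
        return self.pixels[..., 1].astype(float)

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[..., 2].astype(float)


@dataclass
class GridGeometry:
    """Detected colony-grid geometry: one center per expected position.

    ``centers[(row, col)] = (x, y)`` in pixel coordinates, 0-based and
    row-major from the image's top-left. x increases along columns, y
    along rows.
    """

    centers: dict[tuple[int, int], tuple[float, float]]
    mean_spacing_px: float
    colony_radius_px: float
    n_rows: int = field(default=0)
    n_cols: int = field(default=0)

    def __post_init__(self):
        if not self.n_rows:
            self.n_rows = 1 + max(rc[0] for rc in self.centers)
        if not self.n_cols:
            self.n_cols = 1 + max(rc[1] for rc in self.centers)

    def validate(self, image: PlateImage) -> None:
        h, w = image.pixels.shape[:2]
        xs = np.array([[self.centers[(i, j)][0] for j in range(self.n_cols)]
                       for i in range(self.n_rows)])
        ys = np.array([[self.centers[(i, j)][1] for j in range(self.n_cols)]
                       for i in range(self.n_rows)])
        if not (np.all(np.diff(xs, axis=1) > 0) and np.all(np.diff(ys, axis=0) > 0)):
            raise ValueError("grid centers must increase along columns (x) and rows (y)")
        if xs.min() < 0 or ys.min() < 0 or xs.max() >= w or ys.max() >= h:
            raise ValueError("grid centers fall outside the image")


class GridNotFound(RuntimeError):
    """Raised when too few periodic intensity peaks exist to place the grid."""
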