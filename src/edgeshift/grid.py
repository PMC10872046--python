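"""Planar square-grid geometry.

Coordinates are planar eastings/northings in meters (the Finnish uniform
coordinate convention: northings around 6.6-7.7 million meters).  Cells are
half-open squares ``[x, x + cell_size) x [y, y + cell_size)`` indexed
row-major from the lower-left origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidGridError(ValueError):
    """Raised for degenerate grid specifications."""


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a square analysis grid.

    Parameters
    ----------
    x_min, y_min, x_max, y_max
        Grid extent in meters.  ``x_max``/``y_max`` are exclusive upper
        bounds of the covered area.
    cell_size
        Cell edge length in meters (default 10 km).
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    cell_size: float = 10_000.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidGridError(f"cell_size must be > 0, got {self.cell_size}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InvalidGridError(
                "grid extent must satisfy x_max > x_min and y_max > y_min"
            )

    @property
    def n_cols(self) -> int:
        return int(np.ceil((self.x_max - self.x_min) / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(np.ceil((self.y_max - self.y_min) / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, easting, northing):
        """Map point coordinates to row-major cell ids.

        Points outside the extent map to -1.  Boundaries follow the
        half-open convention: a point exactly on a shared edge belongs to
        the cell whose lower-left corner it touches.
        """
        x = np.asarray(easting, dtype=float)
        y = np.asarray(northing, dtype=float)
        ix = np.floor((x - self.x_min) / self.cell_size).astype(np.int64)
        iy = np.floor((y - self.y_min) / self.cell_size).astype(np.int64)
        inside = (ix >= 0) & (ix < self.n_cols) & (iy >= 0) & (iy < self.n_rows)
        out = np.where(inside, iy * self.n_cols + ix, -1)
        return out if out.ndim else int(out)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroid eastings and northings for every cell, in id order."""
        ix = np.arange(self.n_cols)
        iy = np.arange(self.n_rows)
        gx, gy = np.meshgrid(ix, iy)  # row-major: iy varies slowest
        cx = self.x_min + (gx.ravel() + 0.5) * self.cell_size
        cy = self.y_min + (gy.ravel() + 0.5) * self.cell_size
        return cx, cy

    def cell_centroid(self, cell_id):
        """Centroid coordinates for given row-major cell ids."""
        cid = np.asarray(cell_id, dtype=np.int64)
        iy, ix = np.divmod(cid, self.n_cols)
        cx = self.x_min + (ix + 0.5) * self.cell_size
        cy = self.y_min + (iy + 0.5) * self.cell_size
        return cx, cy
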