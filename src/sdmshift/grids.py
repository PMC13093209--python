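"""Geographic grid specification shared by every raster-backed container.

All grids are plain WGS84 geographic lattices: equally spaced in degrees,
row 0 at the northern edge, column 0 at the western edge. Cells are
half-open — closed on their west and north edges — so every point inside
the extent maps to exactly one cell, including points that fall on
interior cell boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = 111.195  # pi * R / 180 for R = 6371 km


@dataclass(frozen=True)
class GridSpec:
    """A north-west anchored geographic grid.

    Parameters
    ----------
    origin_lon, origin_lat:
        Coordinates of the grid's north-west corner, decimal degrees.
    resolution:
        Cell size in arcminutes (2.5 by default throughout the pipeline).
    n_rows, n_cols:
        Grid shape; rows run north to south.
    """

    origin_lon: float
    origin_lat: float
    resolution: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (arcminutes)")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        south = self.origin_lat - self.n_rows * self.res_deg
        east = self.origin_lon + self.n_cols * self.res_deg
        if not (-90.0 <= south and self.origin_lat <= 90.0):
            raise ValueError("grid extent exceeds latitude bounds")
        if not (-360.0 <= self.origin_lon and east <= 360.0):
            raise ValueError("grid extent exceeds longitude bounds")

    @property
    def res_deg(self) -> float:
        """Cell size in decimal degrees."""
        return self.resolution / 60.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- cell geometry -----------------------------------------------------

    def cell_index(self, lon, lat):
        """Map coordinates to (row, col) under the half-open cell rule.

        col = floor((lon - origin_lon)/res), row = floor((origin_lat - lat)/res);
        a point on a shared edge belongs to the cell whose west/north edge it
        touches. Returns integer arrays; out-of-extent points get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.res_deg).astype(int)
        row = np.floor((self.origin_lat - lat) / self.res_deg).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_center(self, row, col):
        """Return (lon, lat) of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.res_deg
        lat = self.origin_lat - (row + 0.5) * self.res_deg
        return lon, lat

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.res_deg

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.res_deg

    def contains(self, lon, lat):
        row, _ = self.cell_index(lon, lat)
        return np.asarray(row) >= 0

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row spherical cell area in km^2.

        A(row) = R^2 * dlambda * (sin(phi_north) - sin(phi_south)) on the
        authalic sphere R = 6371 km; constant along a row.
        """
        res_rad = np.radians(self.res_deg)
        lat_north = np.radians(self.origin_lat - np.arange(self.n_rows) * self.res_deg)
        lat_south = lat_north - res_rad
        return EARTH_RADIUS_KM**2 * res_rad * (np.sin(lat_north) - np.sin(lat_south))
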