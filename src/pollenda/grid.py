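"""Regular lon-lat grids and spherical geometry helpers.

Everything downstream (emission, transport, assimilation) lives on a
cell-centered regular longitude-latitude grid.  Cells are indexed
``[j, i]`` = ``[lat, lon]`` row-major, and flattened with ``ravel()`` in
that order wherever a vector view is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered regular lon-lat grid.

    ``nx`` cells span ``[lon_min, lon_max]``, ``ny`` cells span
    ``[lat_min, lat_max]``; cell centers sit half a cell inside the
    bounding box.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2x2 cells")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("grid extent must be positive")

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.nx

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.ny * self.nx

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.nx) + 0.5) * self.dlon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.ny) + 0.5) * self.dlat

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) arrays of cell-center coordinates, shape (ny, nx)."""
        return np.meshgrid(self.lon_centers, self.lat_centers)

    def cell_area_m2(self) -> np.ndarray:
        """Spherical cell area per cell, shape (ny, nx), in m^2."""
        r = EARTH_RADIUS_KM * 1e3
        dlam = np.deg2rad(self.dlon)
        phi_edges = np.deg2rad(self.lat_min + np.arange(self.ny + 1) * self.dlat)
        band = r * r * dlam * (np.sin(phi_edges[1:]) - np.sin(phi_edges[:-1]))
        return np.repeat(band[:, None], self.nx, axis=1)

    def contains(self, lon, lat) -> np.ndarray:
        """True where (lon, lat) lies inside the cell-center hull (so that
        bilinear interpolation is defined without extrapolation)."""
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        lc, tc = self.lon_centers, self.lat_centers
        return (lon >= lc[0]) & (lon <= lc[-1]) & (lat >= tc[0]) & (lat <= tc[-1])

    def bilinear_weights(self, lon: float, lat: float):
        """Flat cell indices and weights of the 4-point bilinear stencil."""
        if not bool(self.contains(lon, lat)):
            raise ValueError(f"point ({lon}, {lat}) outside grid interior")
        lc, tc = self.lon_centers, self.lat_centers
        i = int(np.clip(np.searchsorted(lc, lon) - 1, 0, self.nx - 2))
        j = int(np.clip(np.searchsorted(tc, lat) - 1, 0, self.ny - 2))
        fx = (lon - lc[i]) / (lc[i + 1] - lc[i])
        fy = (lat - tc[j]) / (tc[j + 1] - tc[j])
        idx = np.array(
            [j * self.nx + i, j * self.nx + i + 1,
             (j + 1) * self.nx + i, (j + 1) * self.nx + i + 1]
        )
        w = np.array(
            [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
        )
        return idx, w


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees.

    Broadcasts over array inputs.
    """
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distance_km(lon, lat) -> np.ndarray:
    """Dense pairwise great-circle distance matrix for point sets (km)."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
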