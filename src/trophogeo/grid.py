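"""Regular latitude-longitude world grid with cosine-latitude area weights."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_uniform(values: np.ndarray, name: str) -> None:
    if values.size < 2:
        raise ValueError(f"{name} needs at least two entries")
    steps = np.diff(values)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError(f"{name} spacing is not uniform")


@dataclass(frozen=True)
class WorldGrid:
    """Uniform lat-lon grid of cell centers.

    Latitudes in [-90, 90], longitudes in [-180, 180); the area weight of a
    cell is cos(latitude), strictly positive (cell centers never sit on a
    pole for any resolution that divides 180).
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat_centers", np.asarray(self.lat_centers, dtype=float))
        object.__setattr__(self, "lon_centers", np.asarray(self.lon_centers, dtype=float))
        _check_uniform(self.lat_centers, "lat_centers")
        _check_uniform(self.lon_centers, "lon_centers")
        if self.lat_centers.min() < -90 or self.lat_centers.max() > 90:
            raise ValueError("latitudes outside [-90, 90]")
        if self.lon_centers.min() < -180 or self.lon_centers.max() >= 180:
            raise ValueError("longitudes outside [-180, 180)")

    @classmethod
    def from_resolution(cls, step: float = 5.0) -> "WorldGrid":
        if step <= 0:
            raise ValueError("grid step must be positive")
        lat = np.arange(-90 + step / 2, 90, step)
        lon = np.arange(-180 + step / 2, 180, step)
        return cls(lat, lon)

    @property
    def nlat(self) -> int:
        return self.lat_centers.size

    @property
    def nlon(self) -> int:
        return self.lon_centers.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def n_cells(self) -> int:
        return self.nlat * self.nlon

    @property
    def cell_area_weights(self) -> np.ndarray:
        """cos(latitude) weight per cell, broadcast to the full grid."""
        w = np.cos(np.deg2rad(self.lat_centers))
        if np.any(w <= 0):
            raise ValueError("non-positive area weight (cell center on a pole?)")
        return np.repeat(w[:, None], self.nlon, axis=1)

    @property
    def lat_grid(self) -> np.ndarray:
        return np.repeat(self.lat_centers[:, None], self.nlon, axis=1)

    @property
    def lon_grid(self) -> np.ndarray:
        return np.repeat(self.lon_centers[None, :], self.nlat, axis=0)

    def cell_index(self, flat_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map flat cell indices (row-major) to (ilat, ilon)."""
        flat = np.asarray(flat_index)
        return np.unravel_index(flat, self.shape)


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    """Area-weighted mean over finite cells."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("no finite cells to average")
    w = np.asarray(weights, dtype=float)[finite]
    return float(np.sum(values[finite] * w) / np.sum(w))
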