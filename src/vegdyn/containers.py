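"""Core in-memory containers shared by every pipeline stage.

All rasters live on a single :class:`RasterGrid`. Row 0 is the top of the
map and pixel coordinates refer to pixel *centers*; every module inherits
this convention. Missing data is represented as NaN in memory for float
rasters; the grid's ``nodata`` sentinel is only used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RasterGrid",
    "MonthlyStack",
    "AnnualStack",
    "DriverStack",
    "MaskSet",
    "DRIVER_NAMES",
    "LANDCOVER_LEGEND",
    "EXCLUDED_LANDCOVER",
    "GRASSLAND_LEGEND",
]

#: Canonical driver variable names (annual rasters).
DRIVER_NAMES = ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")

#: Integer legend for the land-cover raster.
LANDCOVER_LEGEND = {
    1: "grassland",
    2: "forest",
    3: "water",
    4: "impervious",
    5: "wetland",
    6: "glacier",
    7: "bare",
}

#: Land-cover classes removed from every analysis surface.
EXCLUDED_LANDCOVER = ("water", "impervious", "wetland", "glacier")

#: Integer legend for the grassland-type raster.
GRASSLAND_LEGEND = {0: "other", 1: "steppe", 2: "meadow"}


@dataclass(frozen=True)
class RasterGrid:
    """A regular, axis-aligned raster grid with square pixels.

    ``origin_x``/``origin_y`` are the map coordinates of the grid's
    top-left *corner*. Grid equality is exact field-by-field equality.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 250.0
    crs_id: str = "local"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of all pixel centers as (x, y) 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def conforms(self, array: np.ndarray) -> bool:
        return array.shape[-2:] == self.shape

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "crs_id": self.crs_id,
            "nodata": self.nodata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RasterGrid":
        return cls(**d)


def _check_conforms(grid: RasterGrid, values: np.ndarray, n_bands: int) -> None:
    if values.ndim != 3 or values.shape != (n_bands, grid.n_rows, grid.n_cols):
        raise ValueError(
            f"values shape {values.shape} does not conform to "
            f"({n_bands}, {grid.n_rows}, {grid.n_cols})"
        )


@dataclass
class MonthlyStack:
    """Monthly NDVI rasters indexed by strictly increasing (year, month)."""

    grid: RasterGrid
    index: list[tuple[int, int]]
    values: np.ndarray  # (n_index, n_rows, n_cols), NaN = nodata

    def __post_init__(self) -> None:
        self.index = [(int(y), int(m)) for y, m in self.index]
        if sorted(self.index) != self.index or len(set(self.index)) != len(self.index):
            raise ValueError("(year, month) index must be strictly increasing")
        if not self.index:
            raise ValueError("empty stack")
        for _, m in self.index:
            if not 1 <= m <= 12:
                raise ValueError(f"month out of range: {m}")
        self.values = np.asarray(self.values, dtype=float)
        _check_conforms(self.grid, self.values, len(self.index))

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.index})


@dataclass
class AnnualStack:
    """One raster per year (NDVI composite, focal CV, or a driver)."""

    grid: RasterGrid
    years: Sequence[int]
    values: np.ndarray  # (n_years, n_rows, n_cols), NaN = nodata

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        if sorted(self.years) != self.years or len(set(self.years)) != len(self.years):
            raise ValueError("years must be strictly increasing")
        if not self.years:
            raise ValueError("empty stack")
        self.values = np.asarray(self.values, dtype=float)
        _check_conforms(self.grid, self.values, len(self.years))


@dataclass
class DriverStack:
    """Six annual driver variables sharing one grid and year axis."""

    grid: RasterGrid
    years: Sequence[int]
    variables: dict[str, np.ndarray]  # name -> (n_years, n_rows, n_cols)

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        for name, arr in self.variables.items():
            if name not in DRIVER_NAMES:
                raise ValueError(f"unknown driver variable {name!r}")
            self.variables[name] = arr = np.asarray(arr, dtype=float)
            _check_conforms(self.grid, arr, len(self.years))

    def as_annual_stack(self, name: str) -> AnnualStack:
        return AnnualStack(self.grid, list(self.years), self.variables[name])


@dataclass
class MaskSet:
    """Boolean exclusion masks; True means the pixel is removed."""

    landcover_mask: np.ndarray
    buffer_mask: np.ndarray
    combined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.landcover_mask = np.asarray(self.landcover_mask, dtype=bool)
        self.buffer_mask = np.asarray(self.buffer_mask, dtype=bool)
        if self.landcover_mask.shape != self.buffer_mask.shape:
            raise ValueError("mask shapes differ")
        combined = self.landcover_mask | self.buffer_mask
        if self.combined is None:
            self.combined = combined
        elif not np.array_equal(np.asarray(self.combined, dtype=bool), combined):
            raise ValueError("combined mask must equal landcover OR buffer")
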