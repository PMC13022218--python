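"""Raster grid model and in-memory band containers.

All imagery in the pipeline lives on a single shared grid (GridSpec):
a north-up, axis-aligned raster with pixel-center registration. A map
point (x, y) falls in pixel (row, col) by the half-open cell rule

    col = floor((x - origin_x) / pixel_size)
    row = floor((origin_y - y) / pixel_size)

i.e. each cell covers [x0, x0 + pixel_size) horizontally and
(y0 - pixel_size, y0] vertically, with origin at the grid's upper-left
corner. No reprojection is supported: every input must share one CRS
label.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

#: Recognised band unit labels.
UNITS = ("reflectance", "dB", "linear_power", "index", "mg_per_L")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid.

    Parameters
    ----------
    origin_x, origin_y : float
        Map coordinates of the grid's upper-left corner.
    pixel_size : float
        Ground sampling distance in map units (default 10 m).
    n_rows, n_cols : int
        Grid dimensions.
    crs_label : str
        Opaque CRS identifier; all grids in a run must share it.
    """

    origin_x: float
    origin_y: float
    pixel_size: float = 10.0
    n_rows: int = 1
    n_cols: int = 1
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a map point.

        Raises ``IndexError`` for points outside the grid extent. Points
        exactly on the right/bottom outer edge are out of bounds by the
        half-open convention.
        """
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        # top/left edges are inclusive: y == origin_y belongs to row 0
        if y == self.origin_y:
            row = 0
        if row < 0 or row >= self.n_rows or col < 0 or col >= self.n_cols:
            raise IndexError(
                f"point ({x}, {y}) outside grid extent {self.extent}"
            )
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        half = self.pixel_size / 2.0
        return (
            self.origin_x + col * self.pixel_size + half,
            self.origin_y - row * self.pixel_size - half,
        )

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs_label": self.crs_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class RasterBand:
    """One named raster band on a GridSpec.

    ``values`` is an (n_rows, n_cols) float array; ``nodata_mask`` is True
    where the pixel carries no observation. Values must be finite wherever
    the mask is False.
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    units: str = "index"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"band '{self.name}': values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata_mask shape does not match grid")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out

    def copy(self, **overrides) -> "RasterBand":
        kw = dict(
            grid=self.grid,
            name=self.name,
            values=self.values.copy(),
            nodata_mask=self.nodata_mask.copy(),
            units=self.units,
        )
        kw.update(overrides)
        return RasterBand(**kw)


@dataclass
class SceneStack:
    """A dated acquisition: several co-registered bands on one grid.

    ``sensor`` is a free label; the pipeline uses "S2" for optical and
    "S1" for SAR stacks.
    """

    date: _dt.date
    bands: dict[str, RasterBand] = field(default_factory=dict)
    sensor: str = "S2"

    def __post_init__(self) -> None:
        grids = {b.grid for b in self.bands.values()}
        if len(grids) > 1:
            raise ValueError("all bands in a SceneStack must share one GridSpec")

    @property
    def grid(self) -> GridSpec:
        if not self.bands:
            raise ValueError("empty SceneStack has no grid")
        return next(iter(self.bands.values())).grid

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    def __getitem__(self, name: str) -> RasterBand:
        return self.bands[name]
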