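"""Core raster containers and the grid contract shared by every stage.

All rasters in the package live on one common pixel grid (``GridSpec``):
0-based, row-major indices referenced to pixel centers, with a square
pixel size in map units (30 m by default, the working resolution of the
mapping framework). Inputs are assumed co-registered; a grid mismatch is
always an error, never a silent resample.

Validity is tracked with a four-valued mask. Cloud and shadow pixels are
treated exactly like nodata in every statistic; the distinction is kept
only for bookkeeping and simulation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Mask codes. Anything other than VALID is excluded from statistics.
VALID = 0
CLOUD = 1
SHADOW = 2
NODATA = 3

#: The six reflective bands (harmonization / migration operate on these),
#: plus the thermal band carried through compositing for NDBaI.
REFLECTIVE_BANDS = ("Bblue", "Bgreen", "Bred", "Bnir", "Bswir1", "Bswir2")
ALL_BANDS = REFLECTIVE_BANDS + ("Btir",)

#: Tolerant surface-reflectance range used for validation warnings.
REFLECTANCE_RANGE = (-0.2, 1.6)
#: Plausible SAR backscatter range in dB.
SAR_DB_RANGE = (-50.0, 10.0)


class GridMismatchError(ValueError):
    """Raised when rasters on different grids are combined."""


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a raster: origin (map coordinates of the outer
    corner of pixel (0, 0)), square pixel size, shape, and a CRS id."""

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "EPSG:32648"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_km2(self) -> float:
        """Area of one pixel in km^2 (30 m pixels -> 9e-4 km^2)."""
        return (self.pixel_size / 1000.0) ** 2

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of pixel (row, col). Rows grow
        southward (decreasing y), the usual north-up raster convention."""
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (row, col) containing map point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def contains_index(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def check_same_grid(*grids: GridSpec) -> GridSpec:
    """Assert all grids are identical; return the common one."""
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridMismatchError(f"grid mismatch: {g} != {first}")
    return first


def _check_shape(name: str, arr: np.ndarray, grid: GridSpec) -> None:
    if arr.shape != grid.shape:
        raise ValueError(
            f"{name} shape {arr.shape} does not match grid {grid.shape}"
        )


@dataclass
class Scene:
    """One dated optical acquisition: named reflectance bands (plus the
    thermal band ``Btir`` in sensor-scaled units), a validity mask, a
    calendar date and the originating sensor."""

    bands: dict[str, np.ndarray]
    mask: np.ndarray
    date: _dt.date
    sensor: str  # TM | ETM+ | OLI | MSI
    grid: GridSpec

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(ALL_BANDS)
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}")
        for name, arr in self.bands.items():
            _check_shape(name, arr, self.grid)
        _check_shape("mask", self.mask, self.grid)

    @property
    def valid(self) -> np.ndarray:
        return self.mask == VALID

    def band_stack(self, names: tuple[str, ...] = REFLECTIVE_BANDS) -> np.ndarray:
        """(len(names), n_rows, n_cols) float array of the named bands."""
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"scene is missing bands: {missing}")
        return np.stack([self.bands[n] for n in names])


@dataclass
class SARScene:
    """One dated dual-pol SAR acquisition (VV/VH backscatter in dB)."""

    vv: np.ndarray
    vh: np.ndarray
    orbit: str  # ascending | descending
    date: _dt.date
    mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        _check_shape("vv", self.vv, self.grid)
        _check_shape("vh", self.vh, self.grid)
        _check_shape("mask", self.mask, self.grid)
        if self.orbit not in ("ascending", "descending"):
            raise ValueError(f"unknown orbit {self.orbit!r}")

    @property
    def valid(self) -> np.ndarray:
        return self.mask == VALID


@dataclass
class LabelRaster:
    """Integer class map. 0 is the nodata sentinel (class ids are >= 1)."""

    values: np.ndarray
    grid: GridSpec
    level: int = 2
    nodata: int = 0

    def __post_init__(self) -> None:
        _check_shape("labels", self.values, self.grid)
        self.values = np.asarray(self.values, dtype=np.int32)

    @property
    def valid(self) -> np.ndarray:
        return self.values != self.nodata

    def histogram(self) -> dict[int, int]:
        ids, counts = np.unique(self.values[self.valid], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass
class Composite:
    """A named stack of per-pixel covariate layers for one (season, year),
    with the per-pixel count of valid observations that fed it. Layers are
    NaN wherever the valid count is zero."""

    layers: dict[str, np.ndarray]
    season: str
    year: int
    valid_count: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            _check_shape(name, arr, self.grid)
        _check_shape("valid_count", self.valid_count, self.grid)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def add_layer(self, name: str, values: np.ndarray) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        _check_shape(name, values, self.grid)
        self.layers[name] = values

    def stack(self, names: list[str] | None = None) -> np.ndarray:
        names = self.layer_names if names is None else names
        return np.stack([self.layers[n] for n in names])

    def merged(self, other: "Composite", prefix: str = "") -> "Composite":
        """New composite with ``other``'s layers appended (optionally
        prefixed). Valid counts are combined as elementwise minimum."""
        check_same_grid(self.grid, other.grid)
        layers = dict(self.layers)
        for name, arr in other.layers.items():
            key = prefix + name
            if key in layers:
                raise ValueError(f"duplicate layer name {key!r}")
            layers[key] = arr
        return Composite(
            layers=layers,
            season=self.season,
            year=self.year,
            valid_count=np.minimum(self.valid_count, other.valid_count),
            grid=self.grid,
        )


def new_mask(grid: GridSpec, code: int = VALID) -> np.ndarray:
    return np.full(grid.shape, code, dtype=np.uint8)
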