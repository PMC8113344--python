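"""Seasonal compositing of optical and SAR scene stacks.

A year of acquisitions is split into a dry season (April–September) and a
wet season (October–March of the following year, labeled by its October
year), and each seasonal stack is reduced to per-pixel covariates:

* **medoid** — at every pixel, the actual observed band vector that
  minimizes the summed Euclidean distance to all other valid observations.
  Unlike a mean or median it always returns a real observation, which
  keeps band ratios physically consistent and suppresses residual cloud
  and shadow artifacts.
* **percentile medoids** — the medoid restricted to the observations
  whose NDVI rank falls in a window around the 20th or 80th percentile,
  capturing the seasonal extremes of the vegetation cycle.
* **standard deviation** per band (population, ddof=0).
* **SAR seasonal means** of VV and VH backscatter (dB) and the normalized
  polarization difference (VH−VV)/(VH+VV) computed from those means.
* **terrain layers** (elevation, Horn slope, aspect) from a DEM.

Cloud, shadow and nodata pixels never contribute to any statistic; a
per-pixel valid-observation count is carried on every composite, and
layers are NaN wherever that count is zero.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .grid import (
    Composite,
    GridSpec,
    REFLECTIVE_BANDS,
    SARScene,
    Scene,
    check_same_grid,
)

DRY = "dry"
WET = "wet"


@dataclass(frozen=True)
class SeasonDefinition:
    """Month sets for the two seasons. The wet season may span the year
    boundary; a wet-season scene is labeled with the year of its first
    wet month (October for the default definition)."""

    dry_months: frozenset[int] = frozenset({4, 5, 6, 7, 8, 9})
    wet_months: frozenset[int] = frozenset({10, 11, 12, 1, 2, 3})

    def __post_init__(self) -> None:
        if self.dry_months | self.wet_months != set(range(1, 13)) or (
            self.dry_months & self.wet_months
        ):
            raise ValueError("seasons must partition the 12 months")

    def season_of(self, date: _dt.date) -> tuple[str, int]:
        """(season, label year) for a calendar date."""
        if date.month in self.dry_months:
            return DRY, date.year
        # wet months before the wrap (>= first wet month) keep their year;
        # months after the wrap belong to the previous year's wet season
        wet_start = min(
            m for m in self.wet_months if m > max(self.dry_months, default=0)
        ) if any(m > max(self.dry_months) for m in self.wet_months) else min(
            self.wet_months
        )
        if date.month >= wet_start:
            return WET, date.year
        return WET, date.year - 1


def partition_by_season(
    scenes: Iterable[Scene | SARScene],
    seasons: SeasonDefinition | None = None,
) -> dict[tuple[str, int], list]:
    """Bucket scenes by (season, label year). Empty buckets simply do not
    appear; every scene lands in exactly one bucket."""
    seasons = seasons or SeasonDefinition()
    buckets: dict[tuple[str, int], list] = {}
    for scene in scenes:
        key = seasons.season_of(scene.date)
        buckets.setdefault(key, []).append(scene)
    return buckets


# ---------------------------------------------------------------------------
# optical composites
# ---------------------------------------------------------------------------


def _stack_scenes(
    scenes: Sequence[Scene], bands: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, GridSpec]:
    """(n_scenes, n_bands, rows, cols) float stack with NaN at invalid
    pixels, plus the (n_scenes, rows, cols) validity array."""
    if not scenes:
        raise ValueError("empty scene list")
    grid = check_same_grid(*[s.grid for s in scenes])
    data = np.stack([s.band_stack(tuple(bands)) for s in scenes]).astype(float)
    valid = np.stack([s.valid for s in scenes])
    data[~valid[:, None, :, :].repeat(len(bands), axis=1)] = np.nan
    return data, valid, grid


def _medoid_select(data: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Index of the medoid observation per pixel (-1 where no
    observation is valid). Ties on the distance sum break to the
    lexicographically smallest band vector, so the choice does not
    depend on scene ordering.

    data: (n, B, R, C) with NaN at invalid pixels; valid: (n, R, C).
    """
    n = data.shape[0]
    sums = np.zeros((n,) + data.shape[2:])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.sqrt(np.sum((data[i] - data[j]) ** 2, axis=0))
            both = valid[i] & valid[j]
            sums[i] += np.where(both, d, 0.0)
    sums[~valid] = np.inf
    # lexsort: last key is primary -> sums first, then bands in order
    keys = tuple(data[:, b] for b in range(data.shape[1] - 1, -1, -1)) + (sums,)
    order = np.lexsort(keys, axis=0)
    idx = order[0]
    idx[~valid.any(axis=0)] = -1
    return idx


def _gather(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Select observation idx per pixel from (n, B, R, C); NaN where -1."""
    n, nb, rows, cols = data.shape
    safe = np.clip(idx, 0, n - 1)
    out = np.take_along_axis(
        data, safe[None, None, :, :].repeat(nb, axis=1), axis=0
    )[0]
    out[:, idx < 0] = np.nan
    return out


def medoid_composite(
    scenes: Sequence[Scene],
    bands: Sequence[str] = REFLECTIVE_BANDS,
    season: str = "",
    year: int | None = None,
    prefix: str = "medoid_",
) -> Composite:
    """Per-pixel medoid of the seasonal stack: the valid observation
    minimizing the summed Euclidean distance (over ``bands``) to all other
    valid observations. A single valid observation is its own medoid."""
    data, valid, grid = _stack_scenes(scenes, bands)
    idx = _medoid_select(data, valid)
    values = _gather(data, idx)
    return Composite(
        layers={prefix + b: values[k] for k, b in enumerate(bands)},
        season=season,
        year=year if year is not None else scenes[0].date.year,
        valid_count=valid.sum(axis=0).astype(np.int32),
        grid=grid,
    )


def percentile_medoid_composite(
    scenes: Sequence[Scene],
    bands: Sequence[str] = REFLECTIVE_BANDS,
    q: float = 20.0,
    window_fraction: float = 1.0 / 3.0,
    season: str = "",
    year: int | None = None,
) -> Composite:
    """Medoid of the observations near the q-th NDVI percentile.

    Valid observations at each pixel are ranked by NDVI (the band's own
    value when NIR/red are not among ``bands``); the nearest-rank position
    of the q-th percentile anchors a window of ceil(V * window_fraction)
    observations, whose medoid is returned. With two or fewer valid
    observations this degenerates to the plain medoid.
    """
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    data, valid, grid = _stack_scenes(scenes, bands)
    n = data.shape[0]

    # ranking score: NDVI when possible, else the single band itself
    if "Bnir" in bands and "Bred" in bands:
        nir = data[:, list(bands).index("Bnir")]
        red = data[:, list(bands).index("Bred")]
        denom = nir + red
        score = np.where(np.abs(denom) > 1e-9, (nir - red) / denom, 0.0)
    else:
        score = data[:, 0].copy()
    score[~valid] = np.inf  # invalid observations sort last

    order = np.argsort(score, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")  # rank of each obs
    count = valid.sum(axis=0)

    with np.errstate(invalid="ignore"):
        anchor = np.rint(q / 100.0 * np.maximum(count - 1, 0)).astype(int)
    width = np.ceil(count * window_fraction).astype(int).clip(1)
    start = np.clip(anchor - (width - 1) // 2, 0, np.maximum(count - width, 0))
    in_window = (ranks >= start) & (ranks < start + width) & valid
    # <=2 valid observations: plain medoid over everything valid
    few = count <= 2
    in_window |= few & valid

    masked = data.copy()
    masked[~in_window[:, None, :, :].repeat(len(bands), axis=1)] = np.nan
    idx = _medoid_select(masked, in_window)
    values = _gather(masked, idx)
    prefix = f"p{int(q)}_"
    return Composite(
        layers={prefix + b: values[k] for k, b in enumerate(bands)},
        season=season,
        year=year if year is not None else scenes[0].date.year,
        valid_count=count.astype(np.int32),
        grid=grid,
    )


def stddev_composite(
    scenes: Sequence[Scene],
    bands: Sequence[str] = REFLECTIVE_BANDS,
    season: str = "",
    year: int | None = None,
) -> Composite:
    """Per-pixel, per-band population standard deviation (ddof=0) over the
    valid observations; fewer than two observations give 0."""
    data, valid, grid = _stack_scenes(scenes, bands)
    count = valid.sum(axis=0)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        std = np.nanstd(data, axis=0, ddof=0)
    std[:, count < 2] = 0.0
    std[:, count == 0] = np.nan
    return Composite(
        layers={"std_" + b: std[k] for k, b in enumerate(bands)},
        season=season,
        year=year if year is not None else scenes[0].date.year,
        valid_count=count.astype(np.int32),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# SAR
# ---------------------------------------------------------------------------


def sar_seasonal_covariates(
    scenes: Sequence[SARScene],
    season: str = "",
    year: int | None = None,
) -> Composite:
    """Seasonal mean VV and VH backscatter (dB) plus the normalized
    polarization difference nd_VHVV = (VH−VV)/(VH+VV) computed from the
    seasonal means. Ascending and descending orbits are kept as separate
    layers (suffixed) when both are present."""
    if not scenes:
        raise ValueError("empty scene list")
    grid = check_same_grid(*[s.grid for s in scenes])
    by_orbit: dict[str, list[SARScene]] = {}
    for s in scenes:
        by_orbit.setdefault(s.orbit, []).append(s)

    layers: dict[str, np.ndarray] = {}
    total_count = np.zeros(grid.shape, dtype=np.int32)
    for orbit, group in sorted(by_orbit.items()):
        suffix = "" if len(by_orbit) == 1 else f"_{orbit[:4]}"
        vv = np.stack([np.where(s.valid, s.vv, np.nan) for s in group])
        vh = np.stack([np.where(s.valid, s.vh, np.nan) for s in group])
        import warnings

        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_vv = np.nanmean(vv, axis=0)
            mean_vh = np.nanmean(vh, axis=0)
        denom = mean_vh + mean_vv
        with np.errstate(invalid="ignore", divide="ignore"):
            nd = np.where(
                np.abs(denom) > 1e-9, (mean_vh - mean_vv) / denom, np.nan
            )
        layers["mean_VV" + suffix] = mean_vv
        layers["mean_VH" + suffix] = mean_vh
        layers["nd_VHVV" + suffix] = nd
        total_count += np.sum([s.valid for s in group], axis=0).astype(np.int32)
    return Composite(
        layers=layers,
        season=season,
        year=year if year is not None else scenes[0].date.year,
        valid_count=total_count,
        grid=grid,
    )


def _masked_local_mean(
    values: np.ndarray, valid: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean over valid pixels in a window x window neighborhood."""
    v = np.where(valid, values, 0.0)
    s = ndimage.uniform_filter(v, size=window, mode="reflect")
    c = ndimage.uniform_filter(valid.astype(float), size=window, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(c > 0, s / c, np.nan)
    return mean, c


def lee_filter(scene: SARScene, window: int = 5, noise_var: float | None = None) -> SARScene:
    """Classic Lee speckle filter applied to both polarizations.

    out = m + W (x − m) with local mean m, local variance v and gain
    W = v / (v + noise_var). The noise variance defaults to the mean of
    the local variances over the valid image, the usual adaptive choice.
    The mask is preserved; invalid pixels never enter the statistics.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")

    def _filter_band(values: np.ndarray) -> np.ndarray:
        valid = scene.valid
        mean, _ = _masked_local_mean(values, valid, window)
        mean_sq, _ = _masked_local_mean(values**2, valid, window)
        var = np.maximum(mean_sq - mean**2, 0.0)
        nv = noise_var
        if nv is None:
            nv = float(np.nanmean(np.where(valid, var, np.nan)))
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(var + nv > 0, var / (var + nv), 0.0)
        out = np.array(values, dtype=float)
        out[valid] = (mean + w * (values - mean))[valid]
        return out

    return SARScene(
        vv=_filter_band(scene.vv),
        vh=_filter_band(scene.vh),
        orbit=scene.orbit,
        date=scene.date,
        mask=scene.mask.copy(),
        grid=scene.grid,
    )


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------


def terrain_covariates(dem: np.ndarray, grid: GridSpec) -> Composite:
    """Elevation plus slope and aspect (degrees) by Horn's eight-neighbor
    finite differences. Aspect is the azimuth of the down-slope direction,
    degrees clockwise from north in [0, 360); flat cells are NaN."""
    dem = np.asarray(dem, dtype=float)
    if dem.shape != grid.shape:
        raise ValueError("DEM shape does not match grid")
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError("grid must be at least 3x3 for terrain derivatives")

    z = np.pad(dem, 1, mode="edge")
    cell = grid.pixel_size
    # neighbors:  a b c
    #             d e f      (rows increase southward)
    #             g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                 f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)      # east
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)      # north
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[flat] = np.nan
    return Composite(
        layers={"elevation": dem, "slope": slope, "aspect": aspect},
        season="",
        year=0,
        valid_count=np.ones(grid.shape, dtype=np.int32),
        grid=grid,
    )
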