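"""Post-classification change analysis over a series of label maps.

Given independently classified annual maps on one grid, this module
derives the change products: a per-pixel count of label transitions
(change frequency), class-area time series (km², from the pixel size),
annualized net-change rates

    p = 100 * (A_t2 − A_t1) / (A_t1 * (t2 − t1))   [% per year]

with an optional 0–100 min-max rescaling of absolute rates to rank the
most dynamic classes, and area-flow transition matrices between two
dates suitable for Sankey diagrams. Pixels that are nodata in any
compared year are excluded from every count and transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, LabelRaster, check_same_grid


@dataclass
class TransitionMatrix:
    """K x K areas (km²): rows = class at t1, columns = class at t2,
    over the jointly valid pixels."""

    areas: np.ndarray
    class_ids: np.ndarray
    year_from: int
    year_to: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.areas, index=self.class_ids, columns=self.class_ids
        )

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def _check_series(maps: Sequence[LabelRaster]) -> GridSpec:
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    levels = {m.level for m in maps}
    if len(levels) > 1:
        raise ValueError(f"maps mix taxonomy levels: {sorted(levels)}")
    return check_same_grid(*[m.grid for m in maps])


def change_frequency(maps: Sequence[LabelRaster]) -> np.ndarray:
    """Per-pixel count of label changes between consecutive maps.

    Integer array in [0, len(maps) − 1]; −1 marks pixels that are nodata
    in any year.
    """
    grid = _check_series(maps)
    count = np.zeros(grid.shape, dtype=np.int32)
    all_valid = np.ones(grid.shape, dtype=bool)
    for m in maps:
        all_valid &= m.valid
    for prev, nxt in zip(maps[:-1], maps[1:]):
        count += (prev.values != nxt.values) & all_valid
    count[~all_valid] = -1
    return count


def area_series(
    maps: Sequence[LabelRaster],
    years: Sequence[int],
    pixel_area_km2: float | None = None,
    class_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Class areas (km²) per year: valid-pixel count times pixel area.
    Every requested class appears in every year, absent classes as 0."""
    if len(maps) != len(years):
        raise ValueError("one year label per map required")
    grid = check_same_grid(*[m.grid for m in maps])
    px = pixel_area_km2 if pixel_area_km2 is not None else grid.pixel_area_km2
    if class_ids is None:
        ids: set[int] = set()
        for m in maps:
            ids.update(m.histogram())
        class_ids = sorted(ids)
    records = []
    for m, year in zip(maps, years):
        hist = m.histogram()
        for cid in class_ids:
            records.append(
                {
                    "class_id": cid,
                    "year": year,
                    "area_km2": hist.get(cid, 0) * px,
                }
            )
    return pd.DataFrame(records)


def net_change_percent(
    areas: pd.DataFrame, class_id: int, t1: int, t2: int
) -> float:
    """Annualized percentage net change of one class between two years
    (positive = gain). NaN when the class had zero area at t1."""
    if t1 >= t2:
        raise ValueError("t1 must precede t2")

    def _area(t):
        sub = areas[(areas["class_id"] == class_id) & (areas["year"] == t)]
        if sub.empty:
            raise KeyError(f"no area entry for class {class_id}, year {t}")
        return float(sub["area_km2"].iloc[0])

    a1, a2 = _area(t1), _area(t2)
    if a1 == 0:
        return float("nan")
    return 100.0 * (a2 - a1) / (a1 * (t2 - t1))


def rescale_rates(rates: Sequence[float]) -> np.ndarray:
    """Min-max rescale of absolute rates onto [0, 100] to rank dynamism;
    all-equal input maps to all zeros."""
    rates = np.asarray(list(rates), dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate list")
    magnitude = np.abs(rates)
    span = magnitude.max() - magnitude.min()
    if span == 0:
        return np.zeros_like(magnitude)
    return (magnitude - magnitude.min()) / span * 100.0


def transition_matrix(
    map_t1: LabelRaster,
    map_t2: LabelRaster,
    pixel_area_km2: float | None = None,
    class_ids: Sequence[int] | None = None,
    year_from: int = 0,
    year_to: int = 0,
) -> TransitionMatrix:
    """Area flow from each t1 class to each t2 class over the pixels
    valid in both years."""
    grid = check_same_grid(map_t1.grid, map_t2.grid)
    if map_t1.level != map_t2.level:
        raise ValueError("maps are at different taxonomy levels")
    px = pixel_area_km2 if pixel_area_km2 is not None else grid.pixel_area_km2
    joint = map_t1.valid & map_t2.valid
    a = map_t1.values[joint]
    b = map_t2.values[joint]
    if class_ids is None:
        class_ids = sorted(set(np.unique(a)) | set(np.unique(b)))
    class_ids = np.asarray(class_ids)
    pos = {int(c): i for i, c in enumerate(class_ids)}
    k = len(class_ids)
    counts = np.zeros((k, k), dtype=np.int64)
    pair, n = np.unique(np.stack([a, b]), axis=1, return_counts=True)
    for (ca, cb), cnt in zip(pair.T, n):
        counts[pos[int(ca)], pos[int(cb)]] = cnt
    return TransitionMatrix(
        areas=counts * px,
        class_ids=class_ids,
        year_from=year_from,
        year_to=year_to,
    )


def sankey_links(
    tm: TransitionMatrix,
    min_area: float = 0.0,
    include_diagonal: bool = False,
) -> list[tuple[int, int, float]]:
    """(from, to, area) flows at least ``min_area``, sorted descending by
    area — the input for a Sankey diagram. Diagonal (no-change) flows are
    excluded by default."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    links = []
    for i, ci in enumerate(tm.class_ids):
        for j, cj in enumerate(tm.class_ids):
            if i == j and not include_diagonal:
                continue
            area = float(tm.areas[i, j])
            if area >= min_area and area > 0:
                links.append((int(ci), int(cj), area))
    return sorted(links, key=lambda l: -l[2])
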