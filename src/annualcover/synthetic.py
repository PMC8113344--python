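"""Synthetic multi-year, two-season, multi-sensor scene simulator.

Generates the full input side of the mapping pipeline with known truth:
a spatially coherent class map, per-class optical spectra with seasonal
offsets and Gaussian band noise, dual-pol SAR backscatter in dB, patchy
cloud/shadow masking of the optical scenes (SAR is unaffected by cloud),
and scripted between-year class changes. Every stage of the pipeline —
compositing, indices, migration, fusion classification, accuracy and
change analysis — is exercisable against this generator without any
satellite download, and everything is deterministic under a seed.

The generator emulates the statistical structure the method relies on
(distinct class signatures, seasonal contrast, data gaps); it does not
attempt radiative-transfer realism, sensor geometry, or spatially
correlated noise (an option hook exists for band-correlated noise).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .grid import (
    ALL_BANDS,
    CLOUD,
    GridSpec,
    LabelRaster,
    NODATA,
    REFLECTIVE_BANDS,
    SARScene,
    Scene,
    VALID,
    new_mask,
)

#: months used for the synthetic acquisitions of each season
_DRY_MONTHS = (4, 6, 8, 5, 7, 9)
_WET_MONTHS = (10, 12, 2, 11, 1, 3)


@dataclass
class ClassSpectraModel:
    """Per-class signal model: six-band dry-season mean reflectance, an
    additive wet-season offset, SAR backscatter means (VV, VH in dB) with
    a wet-season offset, independent Gaussian noise per band, and a
    thermal mean."""

    class_ids: np.ndarray
    means: np.ndarray            # (K, 6) dry-season reflectance
    seasonal_offsets: np.ndarray  # (K, 6) added in the wet season
    sar_means: np.ndarray        # (K, 2) [VV, VH] dB
    sar_seasonal_offsets: np.ndarray  # (K, 2)
    noise_sd: np.ndarray         # (6,) reflectance
    sar_noise_sd: float          # dB
    thermal_means: np.ndarray    # (K,)
    thermal_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if np.any(self.noise_sd <= 0) or self.sar_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")

    @property
    def min_separation_sd(self) -> float:
        """Minimum pairwise distance between class means in noise-SD
        units: min_ij ||(mu_i − mu_j) / sd||_2."""
        k = len(self.class_ids)
        best = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                d = np.linalg.norm((self.means[i] - self.means[j]) / self.noise_sd)
                best = min(best, d)
        return float(best)

    def index_of(self, class_id: int) -> int:
        pos = np.nonzero(self.class_ids == class_id)[0]
        if len(pos) == 0:
            raise KeyError(f"class id {class_id} not in spectra model")
        return int(pos[0])


def make_class_spectra(
    class_ids: Sequence[int],
    separation: float = 5.0,
    seed: int = 0,
    noise_sd: float = 0.02,
    sar_noise_sd: float = 1.5,
    max_tries: int = 500,
) -> ClassSpectraModel:
    """Draw class mean spectra with a guaranteed minimum pairwise
    separation (in per-band noise-SD units), deterministically by seed.

    Optical means are uniform in a plausible surface-reflectance box;
    the whole draw is rejected and repeated until the separation holds
    (bounded retries, then an error for infeasible requests).
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    class_ids = np.asarray(sorted(class_ids))
    k = len(class_ids)
    sd = np.full(len(REFLECTIVE_BANDS), noise_sd)
    for _ in range(max_tries):
        means = rng.uniform(0.03, 0.55, size=(k, 6))
        ok = True
        for i in range(k):
            for j in range(i + 1, k):
                if np.linalg.norm((means[i] - means[j]) / sd) < separation:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not place {k} class means at separation {separation}"
        )
    offsets = rng.normal(0.0, 0.03, size=(k, 6))
    vv = rng.uniform(-17.0, -6.0, size=k)
    vh = vv - rng.uniform(3.0, 9.0, size=k)
    sar_offsets = rng.normal(0.0, 0.8, size=(k, 2))
    thermal = rng.uniform(280.0, 310.0, size=k)
    return ClassSpectraModel(
        class_ids=class_ids,
        means=means,
        seasonal_offsets=offsets,
        sar_means=np.column_stack([vv, vh]),
        sar_seasonal_offsets=sar_offsets,
        noise_sd=sd,
        sar_noise_sd=sar_noise_sd,
        thermal_means=thermal,
    )


def make_label_map(
    grid: GridSpec,
    class_ids: Sequence[int],
    seed: int = 0,
    seeds_per_class: int = 5,
) -> LabelRaster:
    """Spatially coherent truth map: random seed points per class, each
    pixel labeled by its nearest seed (a Voronoi mosaic)."""
    rng = np.random.default_rng(seed)
    class_ids = np.asarray(sorted(class_ids))
    pts, labels = [], []
    for cid in class_ids:
        for _ in range(seeds_per_class):
            pts.append(
                (rng.uniform(0, grid.n_rows), rng.uniform(0, grid.n_cols))
            )
            labels.append(cid)
    tree = cKDTree(np.asarray(pts))
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    _, nearest = tree.query(
        np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    )
    values = np.asarray(labels)[nearest].reshape(grid.shape).astype(np.int32)
    return LabelRaster(values=values, grid=grid)


def _cloud_mask(
    grid: GridSpec, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Patchy cloud mask: random rectangles accumulated until the target
    cover fraction is reached (rectangles are small relative to the
    scene, so the overshoot stays within a few percent)."""
    mask = new_mask(grid, VALID)
    if fraction <= 0:
        return mask
    covered = np.zeros(grid.shape, dtype=bool)
    max_h = max(2, grid.n_rows // 5)
    max_w = max(2, grid.n_cols // 5)
    while covered.mean() < fraction:
        h = int(rng.integers(2, max_h + 1))
        w = int(rng.integers(2, max_w + 1))
        r0 = int(rng.integers(0, grid.n_rows - h + 1))
        c0 = int(rng.integers(0, grid.n_cols - w + 1))
        covered[r0 : r0 + h, c0 : c0 + w] = True
    mask[covered] = CLOUD
    return mask


def simulate_year(
    model: ClassSpectraModel,
    label_map: LabelRaster,
    year: int,
    scenes_per_season: int = 3,
    cloud_fraction: float = 0.0,
    seed: int = 0,
    sensor: str = "OLI",
    sar_orbit: str = "ascending",
) -> dict[tuple[str, str], list]:
    """Simulate one year of acquisitions for both seasons.

    Returns a dict keyed by ("optical"|"sar", "dry"|"wet") holding scene
    lists. Optical pixel values are class mean (+ wet-season offset)
    plus independent Gaussian band noise, masked by random cloud
    patches; SAR scenes are generated the same way in dB and are never
    cloud-masked.
    """
    if not 0 <= cloud_fraction < 1:
        raise ValueError("cloud_fraction must lie in [0, 1)")
    if not label_map.valid.any():
        raise ValueError("label map is empty")
    rng = np.random.default_rng(seed)
    grid = label_map.grid
    idx = np.zeros(grid.shape, dtype=int)
    for cid in model.class_ids:
        idx[label_map.values == cid] = model.index_of(int(cid))

    out: dict[tuple[str, str], list] = {
        ("optical", "dry"): [],
        ("optical", "wet"): [],
        ("sar", "dry"): [],
        ("sar", "wet"): [],
    }
    for season, months in (("dry", _DRY_MONTHS), ("wet", _WET_MONTHS)):
        wet = season == "wet"
        for s in range(scenes_per_season):
            month = months[s % len(months)]
            date = _dt.date(year + (1 if wet and month <= 3 else 0), month, 15)
            bands: dict[str, np.ndarray] = {}
            base = model.means[idx] + (model.seasonal_offsets[idx] if wet else 0)
            for b, name in enumerate(REFLECTIVE_BANDS):
                bands[name] = base[..., b] + rng.normal(
                    0.0, model.noise_sd[b], size=grid.shape
                )
            bands["Btir"] = model.thermal_means[idx] + rng.normal(
                0.0, model.thermal_noise_sd, size=grid.shape
            )
            mask = _cloud_mask(grid, cloud_fraction, rng)
            mask[~label_map.valid] = NODATA
            out[("optical", season)].append(
                Scene(bands=bands, mask=mask, date=date, sensor=sensor, grid=grid)
            )

            sar_base = model.sar_means[idx] + (
                model.sar_seasonal_offsets[idx] if wet else 0
            )
            sar_mask = new_mask(grid, VALID)
            sar_mask[~label_map.valid] = NODATA
            out[("sar", season)].append(
                SARScene(
                    vv=sar_base[..., 0]
                    + rng.normal(0.0, model.sar_noise_sd, size=grid.shape),
                    vh=sar_base[..., 1]
                    + rng.normal(0.0, model.sar_noise_sd, size=grid.shape),
                    orbit=sar_orbit,
                    date=date,
                    mask=sar_mask,
                    grid=grid,
                )
            )
    return out


@dataclass(frozen=True)
class ChangeEvent:
    """One scripted conversion: in ``year``, a random ``fraction`` of the
    current ``from_class`` pixels (or an explicit region mask) becomes
    ``to_class``."""

    year: int
    from_class: int
    to_class: int
    fraction: float | None = None
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fraction is not None and not 0 <= self.fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        if (self.fraction is None) == (self.region is None):
            raise ValueError("give exactly one of fraction or region")


def apply_change_script(
    label_map: LabelRaster,
    script: Sequence[ChangeEvent],
    years: Sequence[int],
    seed: int = 0,
) -> dict[int, LabelRaster]:
    """Evolve the truth map through the scripted events, returning one
    truth raster per requested year. Events apply cumulatively at their
    year; unchanged pixels keep identical labels across all years."""
    years = sorted(years)
    bad = [e.year for e in script if not years[0] <= e.year <= years[-1]]
    if bad:
        raise ValueError(f"script years outside the simulated range: {bad}")
    rng = np.random.default_rng(seed)
    current = label_map.values.copy()
    truth: dict[int, LabelRaster] = {}
    events = sorted(script, key=lambda e: e.year)
    pos = 0
    for year in years:
        while pos < len(events) and events[pos].year <= year:
            ev = events[pos]
            if ev.region is not None:
                flip = ev.region & (current == ev.from_class)
            else:
                candidates = np.nonzero(current == ev.from_class)
                n = len(candidates[0])
                take = rng.choice(
                    n, size=int(round(ev.fraction * n)), replace=False
                )
                flip = np.zeros_like(current, dtype=bool)
                flip[candidates[0][take], candidates[1][take]] = True
            current[flip] = ev.to_class
            pos += 1
        truth[year] = LabelRaster(
            values=current.copy(), grid=label_map.grid, level=label_map.level
        )
    return truth
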