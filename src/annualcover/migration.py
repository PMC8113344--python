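"""Automatic training-sample migration between years.

Collecting labeled pixels is the expensive step of historical land-cover
mapping. The migration model reuses a well-labeled reference year: a
training pixel is carried to a target year iff its spectrum is deemed
*unchanged* between the two years' composites, judged by two
complementary tests on the six-band reflectance vectors X (reference)
and Y (target):

* Euclidean distance  ED = sqrt(sum_i (X_i − Y_i)^2), sensitive to
  brightness change, retained when ED <= 0.05 (reflectance units);
* spectral angle      SAD = arccos(X·Y / (|X| |Y|)), invariant to
  brightness scaling and sensitive to spectral-shape change.

The published 0.95 threshold for SAD is ambiguous — read literally it is
an angle in radians, but 0.95 is also a natural cosine-similarity cut.
Both readings are implemented (``sad_interpretation``); the default is
the literal angle reading. Threshold comparisons are inclusive and the
two criteria are combined with AND by default (conservative retention,
minimizing label noise in the migrated set).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Composite, REFLECTIVE_BANDS, check_same_grid
from .samples import SamplePoints

ANGLE = "angle_radians"
COSINE = "cosine_similarity"


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two spectral signatures."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signature length mismatch")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("signatures must be finite")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def spectral_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Angle in radians between two signatures, in [0, pi]; invariant to
    positive scaling of either vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signature length mismatch")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm signature")
    cosine = np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)
    return float(np.arccos(cosine))


@dataclass(frozen=True)
class MigrationRule:
    """Retention rule for the unchanged-pixel decision."""

    ed_threshold: float = 0.05
    sad_threshold: float = 0.95
    sad_interpretation: str = ANGLE  # or COSINE
    combiner: str = "AND"  # or "OR"

    def __post_init__(self) -> None:
        if self.ed_threshold <= 0:
            raise ValueError("ed_threshold must be > 0")
        if self.sad_interpretation not in (ANGLE, COSINE):
            raise ValueError(f"unknown sad_interpretation {self.sad_interpretation!r}")
        if self.combiner not in ("AND", "OR"):
            raise ValueError("combiner must be AND or OR")

    def decide(self, ed: np.ndarray, angle: np.ndarray) -> np.ndarray:
        """Vectorized unchanged decision from ED and angle (radians)."""
        ed_ok = np.asarray(ed) <= self.ed_threshold
        if self.sad_interpretation == ANGLE:
            sad_ok = np.asarray(angle) <= self.sad_threshold
        else:
            sad_ok = np.cos(np.asarray(angle)) >= self.sad_threshold
        return ed_ok & sad_ok if self.combiner == "AND" else ed_ok | sad_ok


@dataclass
class MigrationReport:
    n_input: int
    n_retained: int
    n_dropped_nodata: int
    per_class_retention: dict[int, float]
    per_sample: pd.DataFrame  # columns: class_id, ed, sad, kept, nodata

    @property
    def retention_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped_nodata": self.n_dropped_nodata,
            "retention_fraction": self.retention_fraction,
            "per_class_retention": self.per_class_retention,
        }


def signatures_at(
    composite: Composite,
    rows: np.ndarray,
    cols: np.ndarray,
    band_prefix: str = "medoid_",
) -> np.ndarray:
    """(n, 6) reflectance signatures sampled from the composite's band
    layers at the given pixels. NaN rows mark nodata pixels."""
    sigs = np.empty((len(rows), len(REFLECTIVE_BANDS)))
    for k, band in enumerate(REFLECTIVE_BANDS):
        layer = band_prefix + band
        if layer not in composite.layers:
            raise KeyError(f"composite lacks layer {layer!r}")
        sigs[:, k] = composite.layers[layer][rows, cols]
    return sigs


def annual_signature_composite(
    dry: Composite, wet: Composite, band_prefix: str = "medoid_"
) -> Composite:
    """Annual signature source: per-band mean of the dry- and wet-season
    medoids (one season alone where the other is nodata)."""
    check_same_grid(dry.grid, wet.grid)
    import warnings

    layers = {}
    for band in REFLECTIVE_BANDS:
        name = band_prefix + band
        stack = np.stack([dry.layers[name], wet.layers[name]])
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            layers[name] = np.where(
                np.all(np.isnan(stack), axis=0), np.nan, np.nanmean(stack, axis=0)
            )
    return Composite(
        layers=layers,
        season="annual",
        year=dry.year,
        valid_count=dry.valid_count + wet.valid_count,
        grid=dry.grid,
    )


def _pairwise_ed_sad(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ed = np.sqrt(np.sum((x - y) ** 2, axis=1))
    nx = np.linalg.norm(x, axis=1)
    ny = np.linalg.norm(y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.clip(np.sum(x * y, axis=1) / (nx * ny), -1.0, 1.0)
    angle = np.arccos(cosine)
    angle[(nx == 0) | (ny == 0)] = np.nan
    return ed, angle


def migrate_training(
    training: SamplePoints,
    ref_composite: Composite,
    target_composite: Composite,
    rule: MigrationRule | None = None,
    target_year: int | None = None,
    band_prefix: str = "medoid_",
) -> tuple[SamplePoints, MigrationReport]:
    """Carry reference-year training pixels to the target year, keeping
    only those whose spectra the rule deems unchanged. Samples with
    nodata in either year are dropped and reported separately."""
    if len(training) == 0:
        raise ValueError("empty training set")
    rule = rule or MigrationRule()
    check_same_grid(ref_composite.grid, target_composite.grid)
    rows, cols = training.rows, training.cols
    x = signatures_at(ref_composite, rows, cols, band_prefix)
    y = signatures_at(target_composite, rows, cols, band_prefix)

    nodata = ~(np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1))
    ed = np.full(len(training), np.nan)
    angle = np.full(len(training), np.nan)
    ok = ~nodata
    ed[ok], angle[ok] = _pairwise_ed_sad(x[ok], y[ok])

    kept = np.zeros(len(training), dtype=bool)
    decidable = ok & np.isfinite(angle)
    kept[decidable] = rule.decide(ed[decidable], angle[decidable])

    year = target_year if target_year is not None else target_composite.year
    migrated = training.subset(kept, provenance="migrated", year=year)

    per_sample = pd.DataFrame(
        {
            "class_id": training.class_ids,
            "ed": ed,
            "sad": angle,
            "kept": kept,
            "nodata": nodata,
        }
    )
    per_class = {}
    for cid, group in per_sample[~per_sample["nodata"]].groupby("class_id"):
        per_class[int(cid)] = float(group["kept"].mean())
    report = MigrationReport(
        n_input=len(training),
        n_retained=int(kept.sum()),
        n_dropped_nodata=int(nodata.sum()),
        per_class_retention=per_class,
        per_sample=per_sample,
    )
    return migrated, report


def threshold_grid_search(
    training: SamplePoints,
    ref_composite: Composite,
    target_composite: Composite,
    ed_grid: np.ndarray,
    sad_grid: np.ndarray,
    sad_interpretation: str = ANGLE,
    combiner: str = "AND",
    band_prefix: str = "medoid_",
) -> pd.DataFrame:
    """Retention fraction over a grid of (ED, SAD) thresholds — a helper
    for the trial-and-error threshold selection."""
    out = []
    for ed_t, sad_t in itertools.product(ed_grid, sad_grid):
        rule = MigrationRule(
            ed_threshold=float(ed_t),
            sad_threshold=float(sad_t),
            sad_interpretation=sad_interpretation,
            combiner=combiner,
        )
        _, rep = migrate_training(
            training, ref_composite, target_composite, rule,
            band_prefix=band_prefix,
        )
        out.append(
            {
                "ed_threshold": float(ed_t),
                "sad_threshold": float(sad_t),
                "retained": rep.n_retained,
                "retention_fraction": rep.retention_fraction,
            }
        )
    return pd.DataFrame(out)
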