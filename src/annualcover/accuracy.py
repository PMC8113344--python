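"""Stratified accuracy assessment of classified maps.

Validation follows the standard confusion-matrix protocol: a fixed number
of points (1050 by default) is drawn uniformly without replacement from
each *mapped* class, reference labels are compared against mapped labels,
and the matrix (rows = reference, columns = map) yields:

* OA — overall accuracy, 100 * trace / total;
* PA_k — producer accuracy, 100 * diag_k / row-sum_k (1 − omission);
* UA_k — user accuracy, 100 * diag_k / col-sum_k (1 − commission);
* F1_k — harmonic mean of PA and UA, reported on the 0–1 scale;
* SEM_k — binomial standard error of UA, 100 * sqrt(ua(1−ua)/col-sum_k);
* KC — kappa coefficient on the 0–100 scale;
* a 95% binomial half-width for OA.

Zero-denominator cells are reported as NaN (missing), never as 0. The
two-level class system is supported by aggregating an 18-class matrix or
label map onto its 10-class parents, which conserves total counts.

The packaged reference matrices for the 2020 map (level 1 and level 2)
load via :func:`load_reference_confusion`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .grid import LabelRaster
from .samples import SamplePoints
from .taxonomy import ClassTaxonomy

Z_95 = 1.96


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = reference class, columns = mapped class."""

    counts: np.ndarray
    class_ids: np.ndarray
    level: int = 2
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_ids = np.asarray(self.class_ids)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K class ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = self.class_names or [str(c) for c in self.class_ids]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class MetricsTable:
    """Per-class and global accuracy metrics (percent scales except F1)."""

    per_class: pd.DataFrame  # columns: class_id, PA, UA, F1, SEM
    oa: float
    kappa: float
    oa_ci95_half_width: float

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        df.attrs.update(
            {"OA": self.oa, "KC": self.kappa, "OA_CI95": self.oa_ci95_half_width}
        )
        return df


def stratified_sample(
    labels: LabelRaster, n_per_class: int, seed: int
) -> SamplePoints:
    """Draw ``n_per_class`` pixels uniformly without replacement from
    each mapped class (all of a class's pixels, with a warning, when it
    has fewer). Deterministic for a given seed."""
    if not labels.valid.any():
        raise ValueError("label raster is empty (all nodata)")
    rng = np.random.default_rng(seed)
    rows_out, cols_out, ids_out = [], [], []
    for class_id in sorted(labels.histogram()):
        rows, cols = np.nonzero(labels.values == class_id)
        n = len(rows)
        if n < n_per_class:
            import warnings

            warnings.warn(
                f"class {class_id} has only {n} pixels "
                f"(< {n_per_class}); using all of them",
                stacklevel=2,
            )
            take = np.arange(n)
        else:
            take = rng.choice(n, size=n_per_class, replace=False)
        take = np.sort(take)
        rows_out.append(rows[take])
        cols_out.append(cols[take])
        ids_out.append(np.full(len(take), class_id))
    return SamplePoints.from_arrays(
        np.concatenate(rows_out),
        np.concatenate(cols_out),
        np.concatenate(ids_out),
        level=labels.level,
        provenance="interpreted",
    )


def confusion(
    pred,
    ref,
    taxonomy: ClassTaxonomy | None = None,
    level: int = 2,
    class_ids=None,
) -> ConfusionMatrix:
    """Count matrix with rows = reference labels, columns = mapped
    labels. The class set comes from the taxonomy at ``level`` unless
    given explicitly."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    if class_ids is None:
        if taxonomy is None:
            class_ids = np.unique(np.concatenate([pred, ref]))
        else:
            class_ids = np.asarray(taxonomy.class_ids(level))
    class_ids = np.asarray(class_ids)
    known = set(class_ids.tolist())
    strange = (set(np.unique(pred)) | set(np.unique(ref))) - known
    if strange:
        raise ValueError(f"labels not in the class set: {sorted(strange)}")
    counts = _sk_confusion(ref, pred, labels=class_ids)
    names = None
    if taxonomy is not None:
        names = [taxonomy.name(int(c), level) for c in class_ids]
    return ConfusionMatrix(counts, class_ids, level=level, class_names=names)


def metrics(cm: ConfusionMatrix) -> MetricsTable:
    """Full metric suite from a confusion matrix (see module docstring
    for definitions). Percentages are on the 0–100 scale; F1 on 0–1."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    diag = np.diag(counts)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(row_sums > 0, 100.0 * diag / row_sums, np.nan)
        ua = np.where(col_sums > 0, 100.0 * diag / col_sums, np.nan)
        f1 = np.where(
            (pa + ua) > 0, 2.0 * pa * ua / (pa + ua) / 100.0, np.nan
        )
        ua_frac = ua / 100.0
        sem = np.where(
            col_sums > 0,
            100.0 * np.sqrt(ua_frac * (1.0 - ua_frac) / col_sums),
            np.nan,
        )

    oa_frac = diag.sum() / total
    p_e = float((row_sums * col_sums).sum()) / total**2
    kappa = 100.0 * (oa_frac - p_e) / (1.0 - p_e) if p_e < 1 else np.nan
    half_width = 100.0 * Z_95 * np.sqrt(oa_frac * (1.0 - oa_frac) / total)

    per_class = pd.DataFrame(
        {
            "class_id": cm.class_ids,
            "name": cm.class_names or [str(c) for c in cm.class_ids],
            "PA": pa,
            "UA": ua,
            "F1": f1,
            "SEM": sem,
        }
    )
    return MetricsTable(
        per_class=per_class,
        oa=100.0 * oa_frac,
        kappa=float(kappa),
        oa_ci95_half_width=float(half_width),
    )


def merge_to_level1(obj, taxonomy: ClassTaxonomy):
    """Aggregate a level-2 confusion matrix or label raster onto the
    level-1 parent classes. Matrix totals are conserved exactly."""
    if isinstance(obj, ConfusionMatrix):
        if obj.level != 2:
            raise ValueError("input must be a level-2 confusion matrix")
        l1_ids = np.asarray(taxonomy.class_ids(1))
        pos = {cid: i for i, cid in enumerate(l1_ids)}
        k1 = len(l1_ids)
        merged = np.zeros((k1, k1), dtype=np.int64)
        for i, ref_id in enumerate(obj.class_ids):
            pi = pos[taxonomy.parent(int(ref_id))]
            for j, map_id in enumerate(obj.class_ids):
                merged[pi, pos[taxonomy.parent(int(map_id))]] += obj.counts[i, j]
        return ConfusionMatrix(
            merged,
            l1_ids,
            level=1,
            class_names=[taxonomy.name(int(c), 1) for c in l1_ids],
        )
    if isinstance(obj, LabelRaster):
        if obj.level != 2:
            raise ValueError("input must be a level-2 label raster")
        out = np.zeros_like(obj.values)
        for l2_id in np.unique(obj.values[obj.valid]):
            out[obj.values == l2_id] = taxonomy.parent(int(l2_id))
        return LabelRaster(values=out, grid=obj.grid, level=1, nodata=obj.nodata)
    raise TypeError(f"cannot merge object of type {type(obj).__name__}")


def load_reference_confusion(level: int, taxonomy: ClassTaxonomy | None = None) -> ConfusionMatrix:
    """The packaged 2020 reference confusion matrices (level 1: 10
    classes, OA 91.6; level 2: 18 classes, OA 84.7), reconstructed from
    the published validation tables."""
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")
    fname = f"confusion_level{level}_2020.csv"
    ref = resources.files("annualcover.data").joinpath(fname)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col=0)
    counts = df.to_numpy(dtype=np.int64)
    names = list(df.columns)
    class_ids = np.arange(1, len(names) + 1)
    return ConfusionMatrix(counts, class_ids, level=level, class_names=names)
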