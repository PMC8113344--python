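"""Four-collection random-forest probability fusion.

The classifier at the heart of the mapping framework. Each of four
covariate collections (optical dry/wet season, SAR dry/wet season, each
with ancillary layers appended) is classified independently by a random
forest that emits per-pixel class-probability vectors ("priors"). The
priors are then fused multiplicatively into a posterior:

    p'(C_k) = c * p(C_k) + (1 − c) / N          (prior adjustment)
    p_c(C_k) = prod_i p'_i(C_k)                 (posterior product)

The adjustment floors every prior at (1 − c)/N (c = 0.7, N = 18 by
default ⇒ floor 1/60), so a single collection voting zero — typically
because a pixel is data-starved in that collection — cannot annihilate
the product against the unanimous vote of the others. A collection that
is nodata at a pixel is skipped entirely (contributes no factor) rather
than entered at the floor; entering floors for absent data would drag
gap pixels toward uniformity. The strict flooring behavior is available
via ``missing="floor"`` for comparison. The mapped label is the argmax
of the posterior (ties broken by lowest class id).

:class:`FusedForestClassifier` packages the scheme as a scikit-learn
estimator over feature matrices (collections as column blocks, NaN
marking per-collection missingness); the raster-level functions wrap it
for composite stacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .grid import Composite, GridSpec, LabelRaster, check_same_grid
from .samples import SamplePoints

logger = logging.getLogger(__name__)

COLLECTION_IDS = ("optical_dry", "optical_wet", "sar_dry", "sar_wet")


@dataclass(frozen=True)
class RFSettings:
    """Forest hyperparameters; everything not listed stays at library
    defaults, as in the reference configuration."""

    n_estimators: int = 200
    max_features: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")

    def make_forest(self, n_features: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=min(self.max_features, n_features),
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class CovariateCollection:
    """One named per-pixel feature stack (a composite's layers, possibly
    with ancillary layers appended)."""

    collection_id: str
    composite: Composite

    @property
    def grid(self) -> GridSpec:
        return self.composite.grid

    @property
    def feature_names(self) -> list[str]:
        return self.composite.layer_names

    def feature_array(self) -> np.ndarray:
        """(rows, cols, F) float array."""
        return np.moveaxis(self.composite.stack(), 0, -1)

    def valid_mask(self) -> np.ndarray:
        """Pixels where every feature is finite."""
        return np.isfinite(self.feature_array()).all(axis=-1)

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.feature_array()[rows, cols, :]

    def select(self, names: list[str]) -> "CovariateCollection":
        comp = Composite(
            layers={n: self.composite.layers[n] for n in names},
            season=self.composite.season,
            year=self.composite.year,
            valid_count=self.composite.valid_count,
            grid=self.grid,
        )
        return CovariateCollection(self.collection_id, comp)


@dataclass
class PriorRaster:
    """Per-pixel class-probability vectors from one collection."""

    probs: np.ndarray  # (rows, cols, K)
    class_ids: np.ndarray
    valid: np.ndarray  # (rows, cols)
    grid: GridSpec
    collection_id: str = ""


@dataclass
class PosteriorRaster:
    """Fused (unnormalized) posterior products and the per-pixel count of
    contributing collections."""

    values: np.ndarray  # (rows, cols, K)
    class_ids: np.ndarray
    contributing: np.ndarray  # (rows, cols) int
    grid: GridSpec

    @property
    def valid(self) -> np.ndarray:
        return self.contributing > 0


# ---------------------------------------------------------------------------
# Eq. 20 / 21 primitives
# ---------------------------------------------------------------------------


def adjust_prior(p, c: float, n_classes: int):
    """Floor-adjust a prior probability: c*p + (1−c)/N.

    Maps [0, 1] onto [(1−c)/N, c + (1−c)/N]; with c = 1 it is the
    identity. Scalar or array ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prior probabilities must lie in [0, 1]")
    if not 0 <= c <= 1:
        raise ValueError("c must lie in [0, 1]")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    out = c * p + (1.0 - c) / n_classes
    return float(out) if out.ndim == 0 else out


def fuse_posterior(
    priors: list[PriorRaster],
    c: float = 0.7,
    n_classes: int | None = None,
    missing: str = "skip",
) -> PosteriorRaster:
    """Multiply floor-adjusted priors across collections.

    ``missing="skip"`` (default): a collection that is nodata at a pixel
    contributes no factor there. ``missing="floor"``: it contributes the
    uniform floor (1−c)/N instead. Pixels where no collection contributes
    are nodata.
    """
    if not priors:
        raise ValueError("no priors to fuse")
    if missing not in ("skip", "floor"):
        raise ValueError("missing must be 'skip' or 'floor'")
    grid = check_same_grid(*[p.grid for p in priors])
    class_ids = priors[0].class_ids
    for p in priors[1:]:
        if not np.array_equal(p.class_ids, class_ids):
            raise ValueError("class order differs between collections")
    n = n_classes if n_classes is not None else len(class_ids)
    floor = (1.0 - c) / n

    product = np.ones(grid.shape + (len(class_ids),))
    contributing = np.zeros(grid.shape, dtype=np.int32)
    for prior in priors:
        adjusted = np.where(
            prior.valid[..., None],
            c * prior.probs + floor,
            floor if missing == "floor" else 1.0,
        )
        product *= adjusted
        contributing += prior.valid.astype(np.int32)
    if missing == "floor":
        # every collection always contributes a factor
        contributing[:] = len(priors)
    product[contributing == 0] = np.nan
    return PosteriorRaster(
        values=product,
        class_ids=np.asarray(class_ids),
        contributing=contributing,
        grid=grid,
    )


def classify(posterior: PosteriorRaster) -> LabelRaster:
    """Argmax labeling of the posterior. Ties break to the lowest class
    id (class ids are stored ascending and argmax returns the first
    maximum); nodata pixels get the 0 sentinel."""
    order = np.argsort(posterior.class_ids)
    vals = posterior.values[..., order]
    ids = np.asarray(posterior.class_ids)[order]
    safe = np.where(np.isnan(vals), -np.inf, vals)
    labels = ids[np.argmax(safe, axis=-1)].astype(np.int32)
    labels[~posterior.valid] = 0
    return LabelRaster(values=labels, grid=posterior.grid)


# ---------------------------------------------------------------------------
# per-collection models
# ---------------------------------------------------------------------------


@dataclass
class CollectionModel:
    """A fitted forest bound to its collection's feature names."""

    collection_id: str
    feature_names: list[str]
    forest: RandomForestClassifier
    class_ids: np.ndarray
    settings: RFSettings


def _training_matrix(
    collection: CovariateCollection, training: SamplePoints
) -> tuple[np.ndarray, np.ndarray]:
    x = collection.values_at(training.rows, training.cols)
    y = training.class_ids
    if not np.isfinite(x).all():
        raise ValueError(
            f"collection {collection.collection_id!r} has non-finite "
            "features at training pixels"
        )
    return x, y


def fit_collection_model(
    collection: CovariateCollection,
    training: SamplePoints,
    settings: RFSettings | None = None,
) -> CollectionModel:
    """Fit one collection's random forest on the training pixels."""
    settings = settings or RFSettings()
    x, y = _training_matrix(collection, training)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    forest = settings.make_forest(x.shape[1])
    forest.fit(x, y)
    return CollectionModel(
        collection_id=collection.collection_id,
        feature_names=list(collection.feature_names),
        forest=forest,
        class_ids=forest.classes_,
        settings=settings,
    )


def prune_features(
    collection: CovariateCollection,
    training: SamplePoints,
    retention: float = 0.95,
    settings: RFSettings | None = None,
) -> CovariateCollection:
    """Drop the least important features: fit one forest, rank features
    by impurity importance, and keep the smallest prefix whose cumulative
    importance reaches ``retention`` (always at least one feature)."""
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    if retention == 1.0:
        return collection
    model = fit_collection_model(collection, training, settings)
    importances = model.forest.feature_importances_
    order = np.argsort(importances)[::-1]
    cumulative = np.cumsum(importances[order])
    n_keep = int(np.searchsorted(cumulative, retention - 1e-12) + 1)
    n_keep = max(1, min(n_keep, len(order)))
    kept = sorted(order[:n_keep])  # preserve original layer order
    names = collection.feature_names
    dropped = [names[i] for i in range(len(names)) if i not in set(kept)]
    if dropped:
        logger.info(
            "pruned %d/%d features from %s: %s",
            len(dropped), len(names), collection.collection_id, dropped,
        )
    return collection.select([names[i] for i in kept])


def predict_priors(
    model: CollectionModel,
    collection: CovariateCollection,
    chunk: int = 65536,
) -> PriorRaster:
    """Per-pixel class-probability vectors for one collection; pixels
    with any non-finite feature are flagged nodata for this collection."""
    if list(collection.feature_names) != model.feature_names:
        raise ValueError(
            "collection features do not match the fitted model: "
            f"{collection.feature_names} vs {model.feature_names}"
        )
    features = collection.feature_array()
    valid = np.isfinite(features).all(axis=-1)
    flat = features[valid]
    probs = np.zeros(collection.grid.shape + (len(model.class_ids),))
    out = np.empty((flat.shape[0], len(model.class_ids)))
    for start in range(0, flat.shape[0], chunk):
        out[start : start + chunk] = model.forest.predict_proba(
            flat[start : start + chunk]
        )
    probs[valid] = out
    return PriorRaster(
        probs=probs,
        class_ids=model.class_ids,
        valid=valid,
        grid=collection.grid,
        collection_id=model.collection_id,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator surface
# ---------------------------------------------------------------------------


class FusedForestClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest probability fusion as a scikit-learn classifier.

    The feature matrix concatenates the covariate collections as column
    blocks described by ``collection_slices`` (mapping name -> (start,
    stop)); with the default ``None`` the whole matrix is a single
    collection and, with ``c=1``, the estimator reduces exactly to one
    random forest. NaNs mark a sample as missing for the collection
    whose block contains them; missing collections are skipped in the
    posterior product (or floored, with ``missing="floor"``).

    Parameters
    ----------
    n_estimators, max_features : forest hyperparameters (max_features is
        clamped per collection to the block width).
    c : fusion constant of the prior adjustment, in [0, 1].
    n_categories : N of the prior adjustment; defaults to the number of
        classes seen in ``fit``.
    missing : "skip" or "floor".
    random_state : seed for every forest.

    Attributes
    ----------
    classes_ : sorted class labels.
    forests_ : dict of fitted per-collection forests.
    collection_slices_ : resolved column blocks.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_features: int = 8,
        c: float = 0.7,
        n_categories: int | None = None,
        collection_slices: dict[str, tuple[int, int]] | None = None,
        missing: str = "skip",
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.c = c
        self.n_categories = n_categories
        self.collection_slices = collection_slices
        self.missing = missing
        self.random_state = random_state

    def _blocks(self, n_features: int) -> dict[str, tuple[int, int]]:
        if self.collection_slices is None:
            return {"all": (0, n_features)}
        return dict(self.collection_slices)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        self.collection_slices_ = self._blocks(X.shape[1])
        self.forests_ = {}
        seed = 0 if self.random_state is None else self.random_state
        for name, (start, stop) in self.collection_slices_.items():
            block = X[:, start:stop]
            rows = np.isfinite(block).all(axis=1)
            if rows.sum() == 0:
                raise ValueError(f"collection {name!r} has no finite samples")
            if len(np.unique(y[rows])) < 2:
                raise ValueError(
                    f"collection {name!r} sees fewer than two classes"
                )
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=min(self.max_features, stop - start),
                random_state=seed,
                n_jobs=1,
            )
            forest.fit(block[rows], y[rows])
            self.forests_[name] = forest
        return self

    def _posterior(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "forests_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        n_cat = self.n_categories or len(self.classes_)
        floor = (1.0 - self.c) / n_cat
        product = np.ones((X.shape[0], len(self.classes_)))
        contributing = np.zeros(X.shape[0], dtype=int)
        for name, (start, stop) in self.collection_slices_.items():
            block = X[:, start:stop]
            rows = np.isfinite(block).all(axis=1)
            probs = np.zeros((X.shape[0], len(self.classes_)))
            if rows.any():
                forest = self.forests_[name]
                raw = forest.predict_proba(block[rows])
                # align forest class order onto self.classes_
                col = np.searchsorted(self.classes_, forest.classes_)
                aligned = np.zeros((int(rows.sum()), len(self.classes_)))
                aligned[:, col] = raw
                probs[rows] = aligned
            adjusted = np.where(
                rows[:, None],
                self.c * probs + floor,
                floor if self.missing == "floor" else 1.0,
            )
            product *= adjusted
            contributing += rows.astype(int)
        if self.missing == "floor":
            contributing[:] = len(self.collection_slices_)
        product[contributing == 0] = np.nan
        return product, contributing

    def predict_proba(self, X):
        """Normalized fused posteriors; rows with no contributing
        collection are NaN."""
        product, contributing = self._posterior(X)
        with np.errstate(invalid="ignore"):
            return product / np.nansum(product, axis=1, keepdims=True)

    def posterior_product(self, X):
        """Unnormalized posterior products (argmax-equivalent)."""
        return self._posterior(X)[0]

    def predict(self, X):
        product, contributing = self._posterior(X)
        if (contributing == 0).any():
            raise ValueError(
                "some samples have no contributing collection; mask them "
                "before prediction"
            )
        return self.classes_[np.argmax(product, axis=1)]
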