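"""Year-by-year orchestration: scenes → composites → indices →
collections → training (ground or migrated) → fused classification →
assessment → change products.

The in-memory functions (:func:`build_collections`,
:func:`classify_year`) are the API; :func:`run_year` / :func:`run_series`
wrap them for a fixture directory written by the simulator (or by any
producer following the same layout), emitting every output with a JSON
provenance sidecar (inputs, parameters, seeds, package version) so any
stage can be re-run from its sidecar alone. Classifying a year never
reads another year's rasters except through migrated training samples.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .accuracy import confusion, metrics, stratified_sample
from .change import area_series, change_frequency, net_change_percent, transition_matrix
from .compositing import (
    DRY,
    WET,
    medoid_composite,
    partition_by_season,
    percentile_medoid_composite,
    sar_seasonal_covariates,
    stddev_composite,
)
from .ensemble import (
    CovariateCollection,
    RFSettings,
    classify,
    fit_collection_model,
    fuse_posterior,
    predict_priors,
    prune_features,
)
from .grid import Composite, LabelRaster
from .indices import compute_all
from .io import (
    read_label_raster,
    read_samples,
    read_sar_scene,
    read_scene,
    write_label_raster,
)
from .migration import MigrationRule, annual_signature_composite, migrate_training
from .samples import SamplePoints
from .taxonomy import ClassTaxonomy

logger = logging.getLogger(__name__)

SEASONS = (DRY, WET)


@dataclass
class PipelineConfig:
    """One config drives a whole run; see ``PipelineConfig.from_yaml``."""

    fixture_dir: Path
    years: list[int]
    reference_year: int
    level: int = 2
    seed: int = 0
    c: float = 0.7
    n_estimators: int = 200
    max_features: int = 8
    prune_retention: float | None = None
    ed_threshold: float = 0.05
    sad_threshold: float = 0.95
    sad_interpretation: str = "angle_radians"
    combiner: str = "AND"
    collections: list[str] = field(
        default_factory=lambda: ["optical_dry", "optical_wet", "sar_dry", "sar_wet"]
    )
    index_names: list[str] | None = None
    n_validation_per_class: int = 200
    missing: str = "skip"
    taxonomy_path: str | None = None

    def __post_init__(self) -> None:
        self.fixture_dir = Path(self.fixture_dir)
        self.years = sorted(self.years)

    @property
    def rf_settings(self) -> RFSettings:
        return RFSettings(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            seed=self.seed,
        )

    @property
    def migration_rule(self) -> MigrationRule:
        return MigrationRule(
            ed_threshold=self.ed_threshold,
            sad_threshold=self.sad_threshold,
            sad_interpretation=self.sad_interpretation,
            combiner=self.combiner,
        )

    def taxonomy(self) -> ClassTaxonomy:
        if self.taxonomy_path:
            return ClassTaxonomy.from_table(self.taxonomy_path)
        return ClassTaxonomy.default()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["fixture_dir"] = str(raw["fixture_dir"])
        with open(path, "w") as f:
            yaml.safe_dump(raw, f)


# ---------------------------------------------------------------------------
# in-memory stages
# ---------------------------------------------------------------------------


def build_optical_collection(
    scenes: list,
    season: str,
    year: int,
    index_names=None,
) -> tuple[CovariateCollection, Composite]:
    """Full optical covariate stack for one season: medoid bands, their
    spectral indices and band ratios, per-band std and the 20th/80th
    NDVI-percentile medoids. Also returns the bare medoid composite
    (the migration signature source)."""
    medoid = medoid_composite(scenes, season=season, year=year)
    # thermal medoid rides along for the bareness index
    tir = medoid_composite(
        scenes, bands=("Btir",), season=season, year=year
    )
    with_tir = medoid.merged(tir)
    full = compute_all(with_tir, names=index_names)
    full = full.merged(stddev_composite(scenes, season=season, year=year))
    full = full.merged(
        percentile_medoid_composite(scenes, q=20, season=season, year=year)
    )
    full = full.merged(
        percentile_medoid_composite(scenes, q=80, season=season, year=year)
    )
    return CovariateCollection(f"optical_{season}", full), medoid


def build_sar_collection(
    scenes: list, season: str, year: int
) -> CovariateCollection:
    comp = sar_seasonal_covariates(scenes, season=season, year=year)
    return CovariateCollection(f"sar_{season}", comp)


def build_collections(
    optical_by_season: dict[str, list],
    sar_by_season: dict[str, list],
    year: int,
    index_names=None,
    ancillary: Composite | None = None,
    wanted: list[str] | None = None,
) -> tuple[dict[str, CovariateCollection], dict[str, Composite]]:
    """Assemble the (up to) four covariate collections for a year.
    Ancillary layers, when given, are appended to every collection.
    Returns the collections plus the per-season optical medoid
    composites used for migration signatures."""
    collections: dict[str, CovariateCollection] = {}
    medoids: dict[str, Composite] = {}
    for season in SEASONS:
        cid = f"optical_{season}"
        if optical_by_season.get(season) and (wanted is None or cid in wanted):
            coll, medoid = build_optical_collection(
                optical_by_season[season], season, year, index_names
            )
            collections[cid] = coll
            medoids[season] = medoid
        cid = f"sar_{season}"
        if sar_by_season.get(season) and (wanted is None or cid in wanted):
            collections[cid] = build_sar_collection(
                sar_by_season[season], season, year
            )
    if ancillary is not None:
        for cid, coll in list(collections.items()):
            collections[cid] = CovariateCollection(
                cid, coll.composite.merged(ancillary)
            )
    if not collections:
        raise ValueError("no covariate collections could be built")
    return collections, medoids


def classify_year(
    collections: dict[str, CovariateCollection],
    training: SamplePoints,
    settings: RFSettings,
    c: float = 0.7,
    n_categories: int | None = None,
    missing: str = "skip",
    prune_retention: float | None = None,
):
    """Train one forest per collection, fuse adjusted priors and label
    by posterior argmax. Returns (labels, posterior, models)."""
    models = {}
    priors = []
    for cid in sorted(collections):
        coll = collections[cid]
        # each collection trains on the samples it validly observes;
        # data gaps are the fusion stage's problem, not the forest's
        finite = np.isfinite(
            coll.values_at(training.rows, training.cols)
        ).all(axis=1)
        subset = training.subset(finite)
        if finite.sum() < len(training):
            logger.info(
                "%s: %d/%d training pixels usable",
                cid, int(finite.sum()), len(training),
            )
        if prune_retention is not None:
            coll = prune_features(coll, subset, prune_retention, settings)
        model = fit_collection_model(coll, subset, settings)
        models[cid] = (model, coll)
        priors.append(predict_priors(model, coll))
    posterior = fuse_posterior(
        priors, c=c, n_classes=n_categories, missing=missing
    )
    labels = classify(posterior)
    return labels, posterior, models


# ---------------------------------------------------------------------------
# file-based orchestration
# ---------------------------------------------------------------------------


def _scene_paths(config: PipelineConfig, year: int):
    scene_dir = config.fixture_dir / "scenes"
    optical = sorted(scene_dir.glob(f"optical_{year}_*.tif"))
    sar = sorted(scene_dir.glob(f"sar_{year}_*.tif"))
    return optical, sar


def _sidecar(path: Path, stage: str, inputs: list, params: dict) -> None:
    sidecar = {
        "stage": stage,
        "inputs": [str(p) for p in inputs],
        "parameters": params,
        "version": __version__,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def _load_year_collections(config: PipelineConfig, year: int):
    optical_paths, sar_paths = _scene_paths(config, year)
    if not optical_paths and not sar_paths:
        raise FileNotFoundError(
            f"no scenes for year {year} under {config.fixture_dir / 'scenes'}"
        )
    optical = partition_by_season([read_scene(p) for p in optical_paths])
    sar = partition_by_season([read_sar_scene(p) for p in sar_paths])
    opt_by_season = {s: optical.get((s, y), []) for s, y in optical}
    sar_by_season = {s: sar.get((s, y), []) for s, y in sar}
    if not sar_by_season:
        logger.info("year %d runs optical-only (no SAR scenes found)", year)
    collections, medoids = build_collections(
        opt_by_season,
        sar_by_season,
        year,
        index_names=config.index_names,
        wanted=config.collections,
    )
    inputs = [*optical_paths, *sar_paths]
    return collections, medoids, inputs


def _training_for_year(config: PipelineConfig, year: int, medoids, taxonomy):
    """Ground training for the reference year; migrated training
    otherwise (reference-year samples filtered by spectral change)."""
    ref_csv = config.fixture_dir / f"training_{config.reference_year}.csv"
    grid = medoids[DRY].grid
    training = read_samples(ref_csv, taxonomy, grid, level=config.level)
    if year == config.reference_year:
        return training, None
    ref_collections, ref_medoids, _ = _load_year_collections(
        config, config.reference_year
    )
    ref_sig = annual_signature_composite(ref_medoids[DRY], ref_medoids[WET])
    target_sig = annual_signature_composite(medoids[DRY], medoids[WET])
    migrated, report = migrate_training(
        training, ref_sig, target_sig, config.migration_rule, target_year=year
    )
    return migrated, report


def run_year(config: PipelineConfig, year: int, out_dir=None):
    """Run every stage for one year; returns (labels, metrics table)."""
    t0 = time.time()
    out_dir = Path(out_dir) if out_dir else config.fixture_dir / "outputs"
    out_dir.mkdir(parents=True, exist_ok=True)
    taxonomy = config.taxonomy()

    collections, medoids, inputs = _load_year_collections(config, year)
    training, migration_report = _training_for_year(
        config, year, medoids, taxonomy
    )
    labels, posterior, _ = classify_year(
        collections,
        training,
        config.rf_settings,
        c=config.c,
        n_categories=taxonomy.n_classes(config.level),
        missing=config.missing,
        prune_retention=config.prune_retention,
    )
    labels.level = config.level
    map_path = out_dir / f"map_{year}.tif"
    write_label_raster(labels, map_path)
    params = {
        "year": year,
        "seed": config.seed,
        "c": config.c,
        "n_estimators": config.n_estimators,
        "max_features": config.max_features,
        "collections": sorted(collections),
        "training_size": len(training),
    }
    if migration_report is not None:
        params["migration"] = migration_report.summary()
    _sidecar(map_path, "classify", inputs, params)

    table = None
    truth_path = config.fixture_dir / f"truth_{year}.tif"
    if truth_path.exists():
        truth = read_label_raster(truth_path)
        points = stratified_sample(
            labels, config.n_validation_per_class, seed=config.seed + year
        )
        pred = labels.values[points.rows, points.cols]
        ref = truth.values[points.rows, points.cols]
        keep = ref != truth.nodata
        cm = confusion(pred[keep], ref[keep], taxonomy, level=config.level)
        table = metrics(cm)
        report_path = out_dir / f"metrics_{year}.csv"
        df = table.per_class.copy()
        df["OA"] = table.oa
        df["KC"] = table.kappa
        df.to_csv(report_path, index=False)
        _sidecar(report_path, "assess", [map_path, truth_path], params)
        logger.info(
            "year %d: OA %.1f%%, KC %.1f (%.1fs)",
            year, table.oa, table.kappa, time.time() - t0,
        )
    return labels, table


def run_series(config: PipelineConfig, out_dir=None):
    """Run all configured years and derive the change products."""
    if len(config.years) < 2:
        raise ValueError("a series needs at least two years")
    out_dir = Path(out_dir) if out_dir else config.fixture_dir / "outputs"
    out_dir.mkdir(parents=True, exist_ok=True)
    maps: dict[int, LabelRaster] = {}
    tables = {}
    for year in config.years:
        maps[year], tables[year] = run_year(config, year, out_dir)

    ordered = [maps[y] for y in config.years]
    freq = change_frequency(ordered)
    freq_raster = LabelRaster(
        values=np.where(freq < 0, 0, freq + 1).astype(np.int32),
        grid=ordered[0].grid,
    )  # stored +1 so the 0 sentinel stays nodata
    write_label_raster(freq_raster, out_dir / "change_frequency.tif")

    areas = area_series(ordered, config.years)
    areas.to_csv(out_dir / "area_series.csv", index=False)

    rates = []
    for cid in sorted(areas["class_id"].unique()):
        for t1, t2 in zip(config.years[:-1], config.years[1:]):
            try:
                rate = net_change_percent(areas, cid, t1, t2)
            except KeyError:
                rate = float("nan")
            rates.append(
                {"class_id": cid, "t1": t1, "t2": t2, "rate_pct_per_year": rate}
            )
    import pandas as pd

    pd.DataFrame(rates).to_csv(out_dir / "net_change_rates.csv", index=False)

    for t1, t2 in zip(config.years[:-1], config.years[1:]):
        tm = transition_matrix(maps[t1], maps[t2], year_from=t1, year_to=t2)
        tm.to_frame().to_csv(out_dir / f"transitions_{t1}_{t2}.csv")
    return maps, tables
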