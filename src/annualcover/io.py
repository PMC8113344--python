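"""Raster, sample-table and result-table I/O.

Rasters are stored as TIFF files carrying the GeoTIFF georeferencing
tags (ModelPixelScale + ModelTiepoint) and a JSON ImageDescription with
the band names, CRS id, nodata sentinel and any scene metadata, so a
write/read round trip reproduces values, mask and grid exactly. All
rasters a run touches must share one grid: a mismatch raises — the
package never resamples silently.

Samples are read from CSV (columns: ``row,col`` or ``x,y``; ``class`` or
``class_id``; optional ``level``, ``year``, ``provenance``) or GeoJSON
(Point features, or Polygon features rasterized to the pixel centers
they cover). Matrices and metric tables go to plain CSV.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, shape
from shapely.prepared import prep

from .grid import (
    Composite,
    GridSpec,
    LabelRaster,
    NODATA,
    SARScene,
    Scene,
    VALID,
    new_mask,
)
from .samples import PROVENANCES, SamplePoints
from .taxonomy import ClassTaxonomy, UnknownClassError

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922

DEFAULT_NODATA = -9999.0


def _geo_extratags(grid: GridSpec) -> list:
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
    ]


def write_raster(
    path,
    data: np.ndarray,
    grid: GridSpec,
    band_names: list[str] | None = None,
    nodata: float | None = None,
    meta: dict | None = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as a
    georeferenced TIFF with a JSON description."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.shape[1:] != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid")
    description = json.dumps(
        {
            "band_names": band_names or [f"band_{i + 1}" for i in range(len(data))],
            "crs_id": grid.crs_id,
            "nodata": nodata,
            "meta": meta or {},
        }
    )
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if len(data) > 1 else None,
        description=description,
        extratags=_geo_extratags(grid),
    )


def read_raster(path) -> tuple[np.ndarray, GridSpec, list[str], dict]:
    """Read a raster written by :func:`write_raster` (or any TIFF with
    the GeoTIFF scale/tiepoint tags). Returns (data (bands, rows, cols),
    grid, band names, info dict with 'nodata' and 'meta')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (1, 1, 0)
        tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else (0, 0, 0, 0, 0, 0)
        try:
            info = json.loads(page.description or "{}")
        except json.JSONDecodeError:
            info = {}
    if data.ndim == 2:
        data = data[None]
    grid = GridSpec(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        pixel_size=float(scale[0]),
        n_rows=data.shape[1],
        n_cols=data.shape[2],
        crs_id=info.get("crs_id", "unknown"),
    )
    band_names = info.get(
        "band_names", [f"band_{i + 1}" for i in range(len(data))]
    )
    return data, grid, band_names, {
        "nodata": info.get("nodata"),
        "meta": info.get("meta", {}),
    }


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

_MASK_BAND = "mask"


def write_scene(scene: Scene, path) -> None:
    names = list(scene.bands) + [_MASK_BAND]
    data = np.stack(
        [scene.bands[n].astype(np.float64) for n in scene.bands]
        + [scene.mask.astype(np.float64)]
    )
    write_raster(
        path,
        data,
        scene.grid,
        band_names=names,
        meta={"date": scene.date.isoformat(), "sensor": scene.sensor},
    )


def read_scene(
    path,
    band_map: dict[str, int] | None = None,
    date: _dt.date | None = None,
    sensor: str = "OLI",
    nodata: float | None = None,
) -> Scene:
    """Read an optical scene.

    ``band_map`` maps Scene band names to 0-based band indices in the
    file; by default bands are taken by their stored names. The mask
    comes from a stored ``mask`` band when present, otherwise pixels
    equal to the nodata value (file metadata, or the ``nodata``
    argument) are flagged; absent both, everything is valid.
    """
    data, grid, names, info = read_raster(path)
    if band_map is not None:
        for name, index in band_map.items():
            if not 0 <= index < len(data):
                raise IndexError(
                    f"band index {index} out of range for {len(data)}-band file"
                )
        bands = {name: data[index].astype(float) for name, index in band_map.items()}
    else:
        bands = {
            n: data[i].astype(float)
            for i, n in enumerate(names)
            if n != _MASK_BAND
        }
    meta = info["meta"]
    if date is None and meta.get("date"):
        date = _dt.date.fromisoformat(meta["date"])
    if date is None:
        raise ValueError("scene date not stored in file; pass date=")
    if _MASK_BAND in names and band_map is None:
        mask = data[names.index(_MASK_BAND)].astype(np.uint8)
    else:
        mask = new_mask(grid, VALID)
        nd = nodata if nodata is not None else info.get("nodata")
        if nd is not None:
            any_nodata = np.zeros(grid.shape, dtype=bool)
            for arr in bands.values():
                any_nodata |= arr == nd
            mask[any_nodata] = NODATA
    return Scene(
        bands=bands,
        mask=mask,
        date=date,
        sensor=meta.get("sensor", sensor),
        grid=grid,
    )


def write_sar_scene(scene: SARScene, path) -> None:
    data = np.stack(
        [scene.vv.astype(float), scene.vh.astype(float), scene.mask.astype(float)]
    )
    write_raster(
        path,
        data,
        scene.grid,
        band_names=["VV", "VH", _MASK_BAND],
        meta={"date": scene.date.isoformat(), "orbit": scene.orbit},
    )


def read_sar_scene(path) -> SARScene:
    data, grid, names, info = read_raster(path)
    meta = info["meta"]
    return SARScene(
        vv=data[names.index("VV")].astype(float),
        vh=data[names.index("VH")].astype(float),
        orbit=meta.get("orbit", "ascending"),
        date=_dt.date.fromisoformat(meta["date"]),
        mask=data[names.index(_MASK_BAND)].astype(np.uint8),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# label rasters and composites
# ---------------------------------------------------------------------------


def write_label_raster(labels: LabelRaster, path) -> None:
    """Single-band integer TIFF; the nodata sentinel (0 by default) is
    recorded in the file description."""
    write_raster(
        path,
        labels.values.astype(np.int32),
        labels.grid,
        band_names=["labels"],
        nodata=labels.nodata,
        meta={"level": labels.level},
    )


def read_label_raster(path) -> LabelRaster:
    data, grid, _, info = read_raster(path)
    nodata = info.get("nodata")
    return LabelRaster(
        values=data[0].astype(np.int32),
        grid=grid,
        level=int(info["meta"].get("level", 2)),
        nodata=int(nodata) if nodata is not None else 0,
    )


def write_composite(composite: Composite, path) -> None:
    names = composite.layer_names + ["valid_count"]
    data = np.stack(
        [composite.layers[n].astype(float) for n in composite.layer_names]
        + [composite.valid_count.astype(float)]
    )
    write_raster(
        path,
        data,
        composite.grid,
        band_names=names,
        meta={"season": composite.season, "year": composite.year},
    )


def read_composite(path) -> Composite:
    data, grid, names, info = read_raster(path)
    meta = info["meta"]
    layers = {
        n: data[i].astype(float)
        for i, n in enumerate(names)
        if n != "valid_count"
    }
    return Composite(
        layers=layers,
        season=meta.get("season", ""),
        year=int(meta.get("year", 0)),
        valid_count=data[names.index("valid_count")].astype(np.int32),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------


def _resolve_class(value, level: int, taxonomy: ClassTaxonomy) -> int:
    if isinstance(value, (int, np.integer)):
        return taxonomy.validate_id(int(value), level)
    return taxonomy.id_of(str(value), level)


def _polygon_pixels(geom, grid: GridSpec) -> list[tuple[int, int]]:
    prepared = prep(geom)
    minx, miny, maxx, maxy = geom.bounds
    r0, _ = grid.index_of(minx, maxy)
    r1, _ = grid.index_of(minx, miny)
    _, c0 = grid.index_of(minx, maxy)
    _, c1 = grid.index_of(maxx, maxy)
    out = []
    for row in range(max(r0, 0), min(r1, grid.n_rows - 1) + 1):
        for col in range(max(c0, 0), min(c1, grid.n_cols - 1) + 1):
            if prepared.covers(Point(*grid.pixel_center(row, col))):
                out.append((row, col))
    return out


def read_samples(
    path,
    taxonomy: ClassTaxonomy,
    grid: GridSpec,
    level: int = 2,
) -> SamplePoints:
    """Read labeled samples from CSV or GeoJSON and validate every
    record against the taxonomy and the grid. Polygon features yield one
    record per pixel center they cover."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        return _read_samples_geojson(path, taxonomy, grid, level)
    df = pd.read_csv(path)
    if "class" not in df.columns and "class_id" not in df.columns:
        raise ValueError("sample CSV needs a 'class' or 'class_id' column")
    if not (
        {"row", "col"}.issubset(df.columns) or {"x", "y"}.issubset(df.columns)
    ):
        raise ValueError("sample CSV needs 'row,col' or 'x,y' columns")
    records = []
    for _, rec in df.iterrows():
        lvl = int(rec.get("level", level))
        cid = _resolve_class(
            rec["class_id"] if "class_id" in df.columns else rec["class"],
            lvl,
            taxonomy,
        )
        if {"row", "col"}.issubset(df.columns):
            row, col = int(rec["row"]), int(rec["col"])
        else:
            row, col = grid.index_of(float(rec["x"]), float(rec["y"]))
        records.append(
            {
                "row": row,
                "col": col,
                "class_id": cid,
                "level": lvl,
                "year": int(rec.get("year", 0)),
                "provenance": str(rec.get("provenance", "ground")),
            }
        )
    return SamplePoints(pd.DataFrame(records)).validate(grid)


def _read_samples_geojson(
    path, taxonomy: ClassTaxonomy, grid: GridSpec, level: int
) -> SamplePoints:
    with open(path) as f:
        collection = json.load(f)
    records = []
    for feature in collection.get("features", []):
        props = feature.get("properties", {})
        lvl = int(props.get("level", level))
        cid = _resolve_class(
            props.get("class_id", props.get("class")), lvl, taxonomy
        )
        geom = shape(feature["geometry"])
        if geom.geom_type == "Point":
            pixels = [grid.index_of(geom.x, geom.y)]
            if not grid.contains_index(*pixels[0]):
                raise ValueError(f"point geometry outside grid: {geom.wkt}")
        elif geom.geom_type in ("Polygon", "MultiPolygon"):
            pixels = _polygon_pixels(geom, grid)
            if not pixels:
                raise ValueError(
                    f"polygon covers no pixel center on the grid: {geom.bounds}"
                )
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
        for row, col in pixels:
            records.append(
                {
                    "row": row,
                    "col": col,
                    "class_id": cid,
                    "level": lvl,
                    "year": int(props.get("year", 0)),
                    "provenance": str(props.get("provenance", "ground")),
                }
            )
    return SamplePoints(pd.DataFrame(records)).validate(grid)


def write_samples(samples: SamplePoints, path) -> None:
    samples.records.to_csv(path, index=False)
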