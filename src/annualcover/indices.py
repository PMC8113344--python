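"""Spectral indices and band ratios computed from a band composite.

Seventeen indices plus five simple band ratios are derived from the six
reflective bands (and the thermal band, for NDBaI). Each formula is
evaluated exactly as printed in its source literature; any pixel where a
required band is missing/NaN, or where a denominator magnitude falls
below 1e-9, becomes NaN rather than an infinity.

The generic "swir" in several formulas is resolved per index: the 1.6 µm
band (swir1) for EBBI, MVI, NDBaI, NDBI, NDPI and UI; the 2.2 µm band
(swir2) for NBR — the standard choice in each index's source literature.
Every choice can be overridden via the ``swir`` argument. Note that with
a common swir band NDBI and UI are the same formula, and NDBI == −NBR.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .grid import Composite

EPS = 1e-9

#: default swir band per swir-using index
_SWIR_DEFAULT = {
    "EBBI": "swir1",
    "MVI": "swir1",
    "NBR": "swir2",
    "NDBaI": "swir1",
    "NDBI": "swir1",
    "NDPI": "swir1",
    "UI": "swir1",
}

RATIO_NAMES = (
    "ratio_blue_green",
    "ratio_red_blue",
    "ratio_red_green",
    "ratio_red_nir",
    "ratio_nir_redswir1",
)

INDEX_NAMES = (
    "ARVI", "DVI", "EBBI", "EVI", "GCI", "MVI", "NBR", "NDBaI", "NDBI",
    "NDPI", "NDTI", "NDVI", "NDWI", "SAVI", "SIPI", "UI", "WRI",
)

#: indices of normalized-difference form, bounded in [-1, 1] for
#: nonnegative inputs
ND_BOUNDED = ("NBR", "NDBaI", "NDBI", "NDPI", "NDTI", "NDVI", "NDWI", "UI")


def _div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(den) > EPS, num / den, np.nan)


def _bands_for(
    composite: Composite, needed: Sequence[str], band_prefix: str
) -> dict[str, np.ndarray]:
    out = {}
    for short in needed:
        layer = band_prefix + "B" + short
        if layer not in composite.layers:
            raise KeyError(
                f"composite lacks layer {layer!r} needed for the index"
            )
        out[short] = composite.layers[layer]
    return out


def compute_index(
    composite: Composite,
    name: str,
    band_prefix: str = "medoid_",
    swir: str | None = None,
) -> np.ndarray:
    """Evaluate one named index on the composite's band layers
    (``band_prefix + Bblue`` etc.). Returns a 2-D float array."""
    if name not in INDEX_NAMES:
        raise KeyError(f"unknown index {name!r}")
    sw = swir or _SWIR_DEFAULT.get(name)

    def b(short: str) -> np.ndarray:
        return _bands_for(composite, [short], band_prefix)[short]

    if name == "ARVI":
        nir, red, blue = b("nir"), b("red"), b("blue")
        return _div(nir - 2 * red + blue, nir + 2 * red + blue)
    if name == "DVI":
        return b("nir") - b("red")
    if name == "EBBI":
        swb, nir = b(sw), b("nir")
        s = swb + nir
        with np.errstate(invalid="ignore"):
            root = np.where(s > 0, np.sqrt(np.maximum(s, 0.0)), np.nan)
        return _div(swb - nir, 10 * root)
    if name == "EVI":
        nir, red, blue = b("nir"), b("red"), b("blue")
        return 2.5 * _div(nir - red, nir + 6 * red - 7.5 * blue + 1)
    if name == "GCI":
        return _div(b("nir"), b("green")) - 1
    if name == "MVI":
        nir, green, swb = b("nir"), b("green"), b(sw)
        return _div(nir - green, swb - green)
    if name == "NBR":
        nir, swb = b("nir"), b(sw)
        return _div(nir - swb, nir + swb)
    if name == "NDBaI":
        swb, tir = b(sw), b("tir")
        return _div(swb - tir, swb + tir)
    if name in ("NDBI", "UI"):
        swb, nir = b(sw), b("nir")
        return _div(swb - nir, swb + nir)
    if name == "NDPI":
        green, swb = b("green"), b(sw)
        return _div(green - swb, green + swb)
    if name == "NDTI":
        red, green = b("red"), b("green")
        return _div(red - green, red + green)
    if name == "NDVI":
        nir, red = b("nir"), b("red")
        return _div(nir - red, nir + red)
    if name == "NDWI":
        green, nir = b("green"), b("nir")
        return _div(green - nir, green + nir)
    if name == "SAVI":
        nir, red = b("nir"), b("red")
        return 1.5 * _div(nir - red, nir + red + 0.5)
    if name == "SIPI":
        nir, blue, red = b("nir"), b("blue"), b("red")
        return _div(nir - blue, nir - red)
    if name == "WRI":
        green, red, nir, blue = b("green"), b("red"), b("nir"), b("blue")
        return _div(green + red + nir, blue)
    raise AssertionError(name)  # pragma: no cover


def compute_band_ratios(
    composite: Composite, band_prefix: str = "medoid_"
) -> dict[str, np.ndarray]:
    """The five simple band ratios: blue/green, red/blue, red/green,
    red/nir and nir/(red*swir1), division-guarded to NaN."""
    bd = _bands_for(
        composite, ["blue", "green", "red", "nir", "swir1"], band_prefix
    )
    return {
        "ratio_blue_green": _div(bd["blue"], bd["green"]),
        "ratio_red_blue": _div(bd["red"], bd["blue"]),
        "ratio_red_green": _div(bd["red"], bd["green"]),
        "ratio_red_nir": _div(bd["red"], bd["nir"]),
        "ratio_nir_redswir1": _div(bd["nir"], bd["red"] * bd["swir1"]),
    }


def compute_all(
    composite: Composite,
    names: Sequence[str] | None = None,
    band_prefix: str = "medoid_",
    ratios: bool = True,
) -> Composite:
    """Return a new composite with the original layers preserved and one
    appended layer per requested index (all 17 by default) plus,
    optionally, the five band ratios. Layer order is deterministic."""
    names = INDEX_NAMES if names is None else tuple(names)
    unknown = set(names) - set(INDEX_NAMES)
    if unknown:
        raise KeyError(f"unknown index names: {sorted(unknown)}")
    layers = dict(composite.layers)
    out = Composite(
        layers=layers,
        season=composite.season,
        year=composite.year,
        valid_count=composite.valid_count,
        grid=composite.grid,
    )
    for name in names:
        out.add_layer(name, compute_index(composite, name, band_prefix))
    if ratios:
        for rname, values in compute_band_ratios(composite, band_prefix).items():
            out.add_layer(rname, values)
    return out
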