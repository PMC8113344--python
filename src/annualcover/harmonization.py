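"""Cross-sensor reflectance harmonization.

Multi-decade optical time series mix sensors (TM, ETM+, OLI, MSI) whose
surface-reflectance scales differ slightly and systematically. To make
spectra comparable across years — a hard requirement for the spectral
distance tests used in training-sample migration — each reflective band
is placed on a common scale with a band-respective linear transform

    r' = slope_b * r + intercept_b.

Two published coefficient sets ship with the package
(``data/harmonization_coefficients.csv``): one placing TM/ETM+ on the OLI
scale, one relating OLI and MSI. Harmonized values are deliberately not
clamped to [0, 1]: the transforms can exceed the nominal range near
saturation and clamping would bias downstream composites. A warning is
logged when values leave the tolerant validity range instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .grid import REFLECTANCE_RANGE, REFLECTIVE_BANDS, Scene

logger = logging.getLogger(__name__)

#: short band keys used in the coefficient table -> Scene band names
_BAND_KEYS = {
    "blue": "Bblue",
    "green": "Bgreen",
    "red": "Bred",
    "nir": "Bnir",
    "swir1": "Bswir1",
    "swir2": "Bswir2",
}

TM_ETM_TO_OLI = "tm_etm_to_oli"
OLI_MSI = "oli_msi"


@dataclass(frozen=True)
class CoefficientSet:
    """Per-band (slope, intercept) pairs for one sensor pair."""

    pair_id: str
    slopes: dict[str, float]       # keyed by Scene band name
    intercepts: dict[str, float]

    def __post_init__(self) -> None:
        expected = set(REFLECTIVE_BANDS)
        if set(self.slopes) != expected or set(self.intercepts) != expected:
            raise ValueError(
                "coefficient set must cover exactly the six reflective bands"
            )
        for band, slope in self.slopes.items():
            if slope == 0:
                raise ValueError(f"zero slope for band {band}")


def load_coefficients(pair_id: str, path=None) -> CoefficientSet:
    """Load a named coefficient set from the packaged table (or a
    user-supplied CSV in the same schema: pair, band, slope, intercept)."""
    if path is None:
        ref = resources.files("annualcover.data").joinpath(
            "harmonization_coefficients.csv"
        )
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    sub = df[df["pair"] == pair_id]
    if sub.empty:
        raise KeyError(f"no coefficient set named {pair_id!r}")
    slopes, intercepts = {}, {}
    for _, row in sub.iterrows():
        band = _BAND_KEYS[row["band"]]
        slopes[band] = float(row["slope"])
        intercepts[band] = float(row["intercept"])
    return CoefficientSet(pair_id=pair_id, slopes=slopes, intercepts=intercepts)


def invert_coefficients(coeffs: CoefficientSet) -> CoefficientSet:
    """Algebraic inverse: (s, i) -> (1/s, -i/s) per band, so applying the
    forward then the inverse transform is the identity."""
    return CoefficientSet(
        pair_id=coeffs.pair_id + "_inverse",
        slopes={b: 1.0 / s for b, s in coeffs.slopes.items()},
        intercepts={
            b: -coeffs.intercepts[b] / s for b, s in coeffs.slopes.items()
        },
    )


def harmonize_scene(scene: Scene, coeffs: CoefficientSet) -> Scene:
    """Apply the band-respective linear transform to the six reflective
    bands at valid pixels. Mask, thermal band and grid are unchanged."""
    missing = [b for b in REFLECTIVE_BANDS if b not in scene.bands]
    if missing:
        raise KeyError(f"scene is missing reflective bands: {missing}")
    valid = scene.valid
    out_bands: dict[str, np.ndarray] = {}
    for name, values in scene.bands.items():
        if name in coeffs.slopes:
            out = np.array(values, dtype=float)
            out[valid] = (
                coeffs.slopes[name] * out[valid] + coeffs.intercepts[name]
            )
            lo, hi = REFLECTANCE_RANGE
            bad = int(np.sum((out[valid] < lo) | (out[valid] > hi)))
            if bad:
                logger.warning(
                    "harmonized band %s has %d pixels outside [%g, %g]",
                    name, bad, lo, hi,
                )
            out_bands[name] = out
        else:
            out_bands[name] = np.array(values, dtype=float)
    return Scene(
        bands=out_bands,
        mask=scene.mask.copy(),
        date=scene.date,
        sensor=scene.sensor,
        grid=scene.grid,
    )
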