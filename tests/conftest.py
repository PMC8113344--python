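"""Shared fixtures: toy scene builder and one session-scoped synthetic
recovery study (two years, four collections, planted change) reused by
the migration, ensemble and acceptance tests."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from annualcover.grid import GridSpec, Scene, new_mask
from annualcover.study import RecoveryStudyResult, run_recovery_study

#: conditions of the synthetic end-to-end study
E2E_SEED = 11


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(500000.0, 2000000.0, 30.0, 8, 8)


def make_scene(
    values: dict[str, float | np.ndarray],
    grid: GridSpec,
    date: dt.date = dt.date(2020, 6, 1),
    sensor: str = "OLI",
    mask: np.ndarray | None = None,
) -> Scene:
    """Constant-band (or explicit-array) toy scene."""
    bands = {}
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        bands[name] = (
            np.full(grid.shape, float(arr)) if arr.ndim == 0 else arr
        )
    return Scene(
        bands=bands,
        mask=mask if mask is not None else new_mask(grid),
        date=date,
        sensor=sensor,
        grid=grid,
    )


@pytest.fixture(scope="session")
def end_to_end() -> RecoveryStudyResult:
    """The study conditions: 6 classes at >= 5 noise-SD separation on a
    128x128 grid, 2 seasons x 3 scenes x (optical + SAR), 30% cloud,
    200 training pixels per class, fixed seed."""
    return run_recovery_study(seed=E2E_SEED)
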