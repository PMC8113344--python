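"""Labeled pixel samples with provenance.

A :class:`SamplePoints` is a thin validated wrapper over a DataFrame with
columns ``row, col, class_id, level, year, provenance`` — 0-based grid
indices, a taxonomy class at the stated level, the acquisition year of
the label, and where the label came from (``ground`` field observation,
``interpreted`` imagery interpretation, or ``migrated`` carried over from
a reference year by the migration model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec
from .taxonomy import ClassTaxonomy

REQUIRED_COLUMNS = ("row", "col", "class_id", "level", "year", "provenance")
PROVENANCES = ("ground", "interpreted", "migrated")


@dataclass
class SamplePoints:
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        bad = set(self.records["provenance"]) - set(PROVENANCES)
        if bad:
            raise ValueError(f"unknown provenance values: {sorted(bad)}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_arrays(
        cls,
        rows: np.ndarray,
        cols: np.ndarray,
        class_ids: np.ndarray,
        level: int = 2,
        year: int = 0,
        provenance: str = "ground",
    ) -> "SamplePoints":
        return cls(
            pd.DataFrame(
                {
                    "row": np.asarray(rows, dtype=int),
                    "col": np.asarray(cols, dtype=int),
                    "class_id": np.asarray(class_ids, dtype=int),
                    "level": level,
                    "year": year,
                    "provenance": provenance,
                }
            )
        )

    def validate(
        self, grid: GridSpec | None = None, taxonomy: ClassTaxonomy | None = None
    ) -> "SamplePoints":
        if grid is not None:
            inside = (
                (self.records["row"] >= 0)
                & (self.records["row"] < grid.n_rows)
                & (self.records["col"] >= 0)
                & (self.records["col"] < grid.n_cols)
            )
            if not inside.all():
                raise ValueError(
                    f"{int((~inside).sum())} sample(s) fall outside the grid"
                )
        if taxonomy is not None:
            for _, rec in self.records.iterrows():
                taxonomy.validate_id(int(rec["class_id"]), int(rec["level"]))
        return self

    @property
    def rows(self) -> np.ndarray:
        return self.records["row"].to_numpy()

    @property
    def cols(self) -> np.ndarray:
        return self.records["col"].to_numpy()

    @property
    def class_ids(self) -> np.ndarray:
        return self.records["class_id"].to_numpy()

    def subset(self, keep: np.ndarray, **overrides) -> "SamplePoints":
        """Boolean-subset the records, optionally overwriting columns
        (e.g. provenance='migrated', year=1995)."""
        df = self.records.loc[np.asarray(keep, dtype=bool)].copy()
        for key, value in overrides.items():
            df[key] = value
        return SamplePoints(df)

    def per_class_counts(self) -> dict[int, int]:
        return self.records["class_id"].value_counts().sort_index().to_dict()
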