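"""Two-level land-cover class system.

The default taxonomy mirrors the mapping framework's class system: a
primary level of 10 dominant land-cover categories (level 1) refined into
18 secondary categories (level 2), with every level-2 class nesting into
exactly one level-1 parent. Both levels are reconfigurable from a plain
table (CSV with columns id, name, level1_id, level1_name).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: level-2 id -> (level-2 name, level-1 id, level-1 name)
_DEFAULT_LEVEL2 = {
    1: ("Residence1", 1, "Residence"),
    2: ("Residence2", 1, "Residence"),
    3: ("RicePaddies", 2, "RicePaddies"),
    4: ("WoodyCrops", 3, "Cropland"),
    5: ("OtherCrops", 3, "Cropland"),
    6: ("InHouseCrops", 3, "Cropland"),
    7: ("Grassland", 4, "Grassland"),
    8: ("BarrenLand", 5, "BarrenLand"),
    9: ("Scrubland", 6, "Scrubland"),
    10: ("DeciduousBroadleafForest", 7, "ForestLand"),
    11: ("EvergreenBroadleafForest", 7, "ForestLand"),
    12: ("EvergreenNeedleleafForest", 7, "ForestLand"),
    13: ("PlantationLand", 7, "ForestLand"),
    14: ("MangroveForest", 7, "ForestLand"),
    15: ("InlandWetland", 8, "Wetland"),
    16: ("OpenWater", 9, "OpenWater"),
    17: ("Aquaculture", 10, "Aquaculture"),
    18: ("BambooAreas", 7, "ForestLand"),
}


class UnknownClassError(KeyError):
    """A class label or id absent from the taxonomy."""


@dataclass
class ClassTaxonomy:
    """Level-2 classes with a total, surjective mapping onto level 1."""

    level2_names: dict[int, str]
    to_level1: dict[int, int]
    level1_names: dict[int, str]

    def __post_init__(self) -> None:
        if set(self.to_level1) != set(self.level2_names):
            raise ValueError("to_level1 must map every level-2 class")
        if set(self.to_level1.values()) != set(self.level1_names):
            raise ValueError("level-1 mapping must be surjective")
        self._name_to_id = {
            (2, name): cid for cid, name in self.level2_names.items()
        }
        self._name_to_id.update(
            {(1, name): cid for cid, name in self.level1_names.items()}
        )

    @classmethod
    def default(cls) -> "ClassTaxonomy":
        return cls(
            level2_names={k: v[0] for k, v in _DEFAULT_LEVEL2.items()},
            to_level1={k: v[1] for k, v in _DEFAULT_LEVEL2.items()},
            level1_names={v[1]: v[2] for v in _DEFAULT_LEVEL2.values()},
        )

    @classmethod
    def from_table(cls, path) -> "ClassTaxonomy":
        """Load from CSV with columns id, name, level1_id, level1_name."""
        df = pd.read_csv(path)
        required = {"id", "name", "level1_id", "level1_name"}
        if not required.issubset(df.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        return cls(
            level2_names=dict(zip(df["id"].astype(int), df["name"])),
            to_level1=dict(zip(df["id"].astype(int), df["level1_id"].astype(int))),
            level1_names=dict(
                zip(df["level1_id"].astype(int), df["level1_name"])
            ),
        )

    # -- queries ---------------------------------------------------------

    def class_ids(self, level: int = 2) -> list[int]:
        names = self.level2_names if level == 2 else self.level1_names
        return sorted(names)

    def n_classes(self, level: int = 2) -> int:
        return len(self.class_ids(level))

    def name(self, class_id: int, level: int = 2) -> str:
        names = self.level2_names if level == 2 else self.level1_names
        try:
            return names[class_id]
        except KeyError:
            raise UnknownClassError(
                f"class id {class_id} not in level-{level} taxonomy"
            ) from None

    def id_of(self, name: str, level: int = 2) -> int:
        try:
            return self._name_to_id[(level, name)]
        except KeyError:
            raise UnknownClassError(
                f"class {name!r} not in level-{level} taxonomy"
            ) from None

    def validate_id(self, class_id: int, level: int = 2) -> int:
        self.name(class_id, level)
        return int(class_id)

    def parent(self, level2_id: int) -> int:
        try:
            return self.to_level1[level2_id]
        except KeyError:
            raise UnknownClassError(
                f"class id {level2_id} not in level-2 taxonomy"
            ) from None
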