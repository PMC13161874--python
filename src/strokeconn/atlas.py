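"""Cortical patch atlas: 84 ico-1 patches mapped to 22 anatomical regions.

The upstream connectivity detector emits directed links between 84 cortical
patches (42 per hemisphere, ids ``L00``..``L41`` and ``R00``..``R41``) tiling
the cortical mantle.  For statistics the patches are grouped into 11
anatomical regions per hemisphere (22 total), with the frontoparietal cortex
(FPC; Desikan-Killiany labels precentral, postcentral, paracentral) assigned
its own region.

Region labels carry the hemisphere as a prefix, e.g. ``"L.fpc"`` and
``"R.medial_temporal"``.  After lesion mirroring (:func:`strokeconn.links.
mirror_for_lesion`) the left hemisphere is ipsilesional by convention, so
``"L."`` regions read as ipsilesional.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PatchAtlas",
    "AtlasSchemaError",
    "load_patch_atlas",
    "default_atlas",
    "FPC_REGION",
    "N_PATCHES",
    "N_REGIONS",
]

FPC_REGION = "fpc"
N_PATCHES = 84
N_REGIONS = 22
_HEMI_PREFIX = {"left": "L", "right": "R"}


class AtlasSchemaError(ValueError):
    """Raised when an atlas table violates the 84-patch / 22-region schema."""


@dataclass(frozen=True)
class PatchAtlas:
    """Mapping of patch ids to hemisphere and anatomical region.

    Attributes
    ----------
    table
        One row per patch with columns ``patch_id``, ``hemisphere``,
        ``dk_label``, ``region``.
    """

    table: pd.DataFrame
    _patch_region: dict = field(init=False, repr=False)
    _patch_hemi: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        _validate(self.table)
        t = self.table
        object.__setattr__(
            self,
            "_patch_region",
            {
                p: f"{_HEMI_PREFIX[h]}.{r}"
                for p, h, r in zip(t["patch_id"], t["hemisphere"], t["region"])
            },
        )
        object.__setattr__(
            self, "_patch_hemi", dict(zip(t["patch_id"], t["hemisphere"]))
        )

    @property
    def patch_ids(self) -> list[str]:
        return list(self.table["patch_id"])

    @property
    def regions(self) -> list[str]:
        """The 22 region labels, left hemisphere first, stable order."""
        seen: list[str] = []
        for hemi in ("left", "right"):
            sub = self.table[self.table["hemisphere"] == hemi]
            for r in sub["region"]:
                lab = f"{_HEMI_PREFIX[hemi]}.{r}"
                if lab not in seen:
                    seen.append(lab)
        return seen

    def region_of(self, patch_id: str) -> str:
        try:
            return self._patch_region[patch_id]
        except KeyError:
            raise KeyError(f"unknown patch id {patch_id!r}") from None

    def hemisphere_of(self, patch_id: str) -> str:
        try:
            return self._patch_hemi[patch_id]
        except KeyError:
            raise KeyError(f"unknown patch id {patch_id!r}") from None

    def is_fpc(self, patch_id: str) -> bool:
        return self.region_of(patch_id).endswith("." + FPC_REGION)

    def patches_in_region(self, region_label: str) -> list[str]:
        return [p for p, r in self._patch_region.items() if r == region_label]


def _validate(table: pd.DataFrame) -> None:
    required = {"patch_id", "hemisphere", "dk_label", "region"}
    missing = required - set(table.columns)
    if missing:
        raise AtlasSchemaError(f"atlas table missing columns: {sorted(missing)}")
    if len(table) != N_PATCHES:
        raise AtlasSchemaError(
            f"atlas must list exactly {N_PATCHES} patches, got {len(table)}"
        )
    if table["patch_id"].duplicated().any():
        dup = table.loc[table["patch_id"].duplicated(), "patch_id"].iloc[0]
        raise AtlasSchemaError(f"duplicate patch id {dup!r}")
    bad_hemi = ~table["hemisphere"].isin(list(_HEMI_PREFIX))
    if bad_hemi.any():
        row = table.index[bad_hemi][0]
        raise AtlasSchemaError(
            f"row {row}: unknown hemisphere code "
            f"{table.loc[row, 'hemisphere']!r} (expected 'left' or 'right')"
        )
    combos = table.groupby(["hemisphere", "region"], sort=False).size()
    if len(combos) != N_REGIONS:
        raise AtlasSchemaError(
            f"atlas must define {N_REGIONS} (hemisphere, region) combinations, "
            f"got {len(combos)}"
        )
    for hemi in _HEMI_PREFIX:
        regs = set(table.loc[table["hemisphere"] == hemi, "region"])
        if FPC_REGION not in regs:
            raise AtlasSchemaError(
                f"hemisphere {hemi!r} has no {FPC_REGION!r} region"
            )


def load_patch_atlas(path) -> PatchAtlas:
    """Load a patch atlas from a TSV mapping table.

    The file must have a header row ``patch_id  hemisphere  dk_label  region``
    (tab separated; ``#`` lines are comments) and exactly 84 patch rows
    forming 22 distinct (hemisphere, region) combinations with an ``fpc``
    region in each hemisphere.

    Raises
    ------
    AtlasSchemaError
        If the table violates the schema; the message names the offending
        row or column.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return PatchAtlas(table)


def default_atlas() -> PatchAtlas:
    """The packaged default 84-patch atlas (a documented reconstruction)."""
    ref = importlib.resources.files("strokeconn.data") / "patch_atlas_84.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_patch_atlas(path)
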