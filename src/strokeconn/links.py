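"""Directed link tables and their aggregation into region-pair count matrices.

Link tables are pandas DataFrames with one row per detected directed
Granger-causal link and columns ``subject``, ``visit`` (1 or 2), ``trial``
(segment index within visit), ``src_patch``, ``dst_patch``.

Region-pair count matrices use the convention row = source region,
column = target region of the directed link; the diagonal holds
within-region links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import FPC_REGION, PatchAtlas

__all__ = [
    "LINK_COLUMNS",
    "RegionPairCounts",
    "FPC_VIEW_REGIONS",
    "mirror_for_lesion",
    "aggregate_to_regions",
    "collapse_to_fpc",
]

LINK_COLUMNS = ["subject", "visit", "trial", "src_patch", "dst_patch"]

#: Region labels of the collapsed frontoparietal view, in matrix order.
#: "Ipsi" is the lesioned hemisphere (left, after mirroring); "ALL" is the
#: union of the 10 non-FPC regions of that hemisphere.
FPC_VIEW_REGIONS = ["Ipsi FPC", "Ipsi ALL", "Contra FPC", "Contra ALL"]


@dataclass
class RegionPairCounts:
    """Per-trial directed region-pair count matrices.

    Attributes
    ----------
    index
        DataFrame with columns ``subject``, ``visit``, ``trial``; row ``k``
        describes ``counts[k]``.
    counts
        Integer array of shape ``(n_trials, R, R)``; entry ``(k, i, j)`` is
        the number of links from region ``regions[i]`` to ``regions[j]`` in
        trial ``k``.
    regions
        The R region labels, in matrix order.
    """

    index: pd.DataFrame
    counts: np.ndarray
    regions: list[str]

    def __post_init__(self) -> None:
        if self.counts.ndim != 3 or self.counts.shape[1] != self.counts.shape[2]:
            raise ValueError("counts must have shape (n_trials, R, R)")
        if self.counts.shape[1] != len(self.regions):
            raise ValueError("counts dimension does not match region list")
        if len(self.index) != self.counts.shape[0]:
            raise ValueError("index length does not match counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format counts: one row per trial x ordered region pair."""
        R = len(self.regions)
        n = self.n_trials
        idx = self.index.loc[self.index.index.repeat(R * R)].reset_index(drop=True)
        src_grid, dst_grid = np.meshgrid(np.arange(R), np.arange(R), indexing="ij")
        src = np.tile(src_grid.ravel(), n)
        dst = np.tile(dst_grid.ravel(), n)
        out = idx
        out["src_region"] = np.asarray(self.regions)[src]
        out["dst_region"] = np.asarray(self.regions)[dst]
        out["count"] = self.counts.reshape(n * R * R)
        return out

    def to_matrix_json(self) -> str:
        """Matrix-per-trial JSON: region labels plus one matrix per trial."""
        import json

        trials = [
            {
                "subject": str(key.subject),
                "visit": int(key.visit),
                "trial": int(key.trial),
                "matrix": self.counts[k].tolist(),
            }
            for k, key in enumerate(self.index.itertuples(index=False))
        ]
        return json.dumps({"regions": list(self.regions), "trials": trials})

    @classmethod
    def from_long(cls, long: pd.DataFrame, regions: list[str]) -> "RegionPairCounts":
        """Inverse of :meth:`to_long` (missing pairs are taken as zero)."""
        pos = {r: i for i, r in enumerate(regions)}
        keys = long[["subject", "visit", "trial"]].drop_duplicates().reset_index(drop=True)
        key_pos = {tuple(row): k for k, row in enumerate(keys.itertuples(index=False))}
        R = len(regions)
        counts = np.zeros((len(keys), R, R), dtype=np.int64)
        k = [key_pos[t] for t in zip(long["subject"], long["visit"], long["trial"])]
        counts[k, long["src_region"].map(pos), long["dst_region"].map(pos)] = long[
            "count"
        ]
        return cls(index=keys, counts=counts, regions=list(regions))


def mirror_for_lesion(
    links: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Reflect patch ids of right-lesion subjects so that left = ipsilesional.

    Subjects with a right-hemisphere lesion have every patch id's hemisphere
    prefix swapped (``L`` <-> ``R``, same within-hemisphere index); links of
    left-lesion subjects pass through unchanged.  The operation is an
    involution.

    Parameters
    ----------
    links
        Link table (see module docstring).
    subjects
        Cohort table with columns ``subject`` and ``lesion_hemisphere``
        (values ``"left"``/``"right"``).

    Raises
    ------
    KeyError
        If a subject in ``links`` is missing from ``subjects``.
    """
    lesion = dict(zip(subjects["subject"], subjects["lesion_hemisphere"]))
    missing = set(links["subject"]) - set(lesion)
    if missing:
        raise KeyError(
            f"subjects missing from covariate table: {sorted(missing)}"
        )
    out = links.copy()
    is_right = out["subject"].map(lesion).eq("right").to_numpy()
    flip = {"L": "R", "R": "L"}
    for col in ("src_patch", "dst_patch"):
        vals = out[col].to_numpy(dtype=object).copy()
        vals[is_right] = [flip[p[0]] + p[1:] for p in vals[is_right]]
        out[col] = vals
    return out


def aggregate_to_regions(
    links: pd.DataFrame, atlas: PatchAtlas
) -> RegionPairCounts:
    """Sum directed links into one 22x22 region-pair matrix per trial.

    Every subject x visit x trial present in ``links`` yields one matrix;
    the matrix total equals the number of links in that trial.  Links
    between patches of the same region land on the diagonal.

    Raises
    ------
    KeyError
        If a patch id is not in the atlas.
    """
    regions = atlas.regions
    pos = {r: i for i, r in enumerate(regions)}
    for col in ("src_patch", "dst_patch"):
        unknown = set(links[col]) - set(atlas.patch_ids)
        if unknown:
            raise KeyError(f"unknown patch ids in {col}: {sorted(unknown)[:5]}")
    keys = (
        links[["subject", "visit", "trial"]]
        .drop_duplicates()
        .sort_values(["subject", "visit", "trial"])
        .reset_index(drop=True)
    )
    key_pos = {tuple(row): k for k, row in enumerate(keys.itertuples(index=False))}
    R = len(regions)
    counts = np.zeros((len(keys), R, R), dtype=np.int64)
    if len(links):
        k = np.fromiter(
            (key_pos[t] for t in zip(links["subject"], links["visit"], links["trial"])),
            dtype=np.int64,
            count=len(links),
        )
        i = links["src_patch"].map(atlas.region_of).map(pos).to_numpy()
        j = links["dst_patch"].map(atlas.region_of).map(pos).to_numpy()
        np.add.at(counts, (k, i, j), 1)
    return RegionPairCounts(index=keys, counts=counts, regions=regions)


def collapse_to_fpc(counts: RegionPairCounts) -> RegionPairCounts:
    """Collapse a 22x22 matrix set to the 4x4 frontoparietal view.

    Input must use the ipsilesional-is-left convention.  Rows/columns are
    pooled into {Ipsi FPC, Ipsi ALL, Contra FPC, Contra ALL} where "ALL" is
    the union of the 10 non-FPC regions of a hemisphere; totals are
    conserved.
    """
    group = np.empty(len(counts.regions), dtype=np.int64)
    for i, r in enumerate(counts.regions):
        hemi, _, name = r.partition(".")
        ipsi = hemi == "L"
        fpc = name == FPC_REGION
        group[i] = {(True, True): 0, (True, False): 1, (False, True): 2, (False, False): 3}[
            (ipsi, fpc)
        ]
    c = counts.counts
    out = np.zeros((c.shape[0], 4, 4), dtype=c.dtype)
    for gi in range(4):
        for gj in range(4):
            out[:, gi, gj] = c[:, group == gi][:, :, group == gj].sum(axis=(1, 2))
    return RegionPairCounts(
        index=counts.index.copy(), counts=out, regions=list(FPC_VIEW_REGIONS)
    )
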