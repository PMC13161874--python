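"""Reading, writing and validation of the pipeline's tabular formats.

Link tables are TSV with header ``subject  visit  trial  src_patch
dst_patch`` (patch ids ``L00``..``L41``, ``R00``..``R41``); cohort tables
are CSV; configuration is YAML.
"""

from __future__ import annotations

import re

import pandas as pd

from .links import LINK_COLUMNS

__all__ = [
    "SchemaError",
    "read_links",
    "write_links",
    "read_cohort",
    "write_cohort",
]

_PATCH_RE = re.compile(r"^[LR](\d{2})$")
_COHORT_COLUMNS = [
    "subject",
    "moca_visit1",
    "moca_visit2",
    "lesion_hemisphere",
    "age",
    "sex",
    "race",
    "education_years",
]


class SchemaError(ValueError):
    """A tabular input violates its schema; the message names the row."""


def _check_patch(value: str, row: int, col: str) -> None:
    m = _PATCH_RE.match(str(value))
    if not m or int(m.group(1)) > 41:
        raise SchemaError(f"row {row}: invalid patch id {value!r} in column {col!r}")


def read_links(path) -> pd.DataFrame:
    """Read and validate a link TSV; row numbers refer to data rows (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    missing = set(LINK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"link table missing columns: {sorted(missing)}")
    df = df[LINK_COLUMNS]
    bad_visit = ~df["visit"].isin([1, 2])
    if bad_visit.any():
        row = int(df.index[bad_visit][0])
        raise SchemaError(f"row {row}: visit must be 1 or 2, got {df.loc[row, 'visit']!r}")
    for col in ("src_patch", "dst_patch"):
        ok = df[col].astype(str).str.match(_PATCH_RE)
        idx = df[col].astype(str).str.extract(_PATCH_RE)[0]
        ok &= pd.to_numeric(idx, errors="coerce").le(41).fillna(False)
        if not ok.all():
            row = int(df.index[~ok][0])
            _check_patch(df.loc[row, col], row, col)
    return df


def write_links(links: pd.DataFrame, path) -> None:
    links[LINK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str})
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns: {sorted(missing)}")
    if df["subject"].duplicated().any():
        dup = df.loc[df["subject"].duplicated(), "subject"].iloc[0]
        raise SchemaError(f"duplicate subject id {dup!r}")
    for col in ("moca_visit1", "moca_visit2"):
        bad = (df[col] < 0) | (df[col] > 30)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"row {row}: {col} outside [0, 30]")
    bad = ~df["lesion_hemisphere"].isin(["left", "right"])
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"row {row}: lesion_hemisphere must be 'left' or 'right', "
            f"got {df.loc[row, 'lesion_hemisphere']!r}"
        )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
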