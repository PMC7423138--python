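"""Delimited-text readers and writers for every table the pipeline consumes.

All tables are tab-separated with a header row. Subject-level tables
(centrality, responses, clinical scores) carry the subject id in the first
column; the domain map is a two-column ``region_id<TAB>domain`` file.
Floats are written at full ``repr`` precision so that a written table
round-trips bit-for-bit, which the pipeline's determinism contract relies on.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .errors import DataError

INDEX_NAME = "subject_id"


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a subject-indexed table (centrality, responses or clinical scores)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input table not found: {path}")
    # round_trip float parsing: a written table must reload bit-identically
    # for the pipeline's mode-equivalence and determinism contracts
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise DataError(f"duplicate subject ids in {path}")
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=df.index.name or INDEX_NAME)


def read_domain_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (region_id, domain) file into a dict."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"domain map not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise DataError(f"domain map must have exactly two columns, got {df.shape[1]}")
    region_col, domain_col = df.columns
    if df[region_col].duplicated().any():
        dupes = df[region_col][df[region_col].duplicated()].tolist()
        raise DataError(f"regions mapped to more than one domain: {dupes}")
    return dict(zip(df[region_col], df[domain_col]))


def write_domain_map(mapping: dict[str, str], path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"region_id": list(mapping), "domain": list(mapping.values())})
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_dir(path: str | os.PathLike) -> "pd.Series":
    """Read one time-series table per subject from a directory.

    Each file is ``<subject_id>.tsv`` with a header row of region ids and one
    row per timepoint. Returns an ordered mapping subject_id -> DataFrame
    (timepoints x regions); subjects are ordered by filename.
    """
    path = Path(path)
    if not path.is_dir():
        raise DataError(f"time-series directory not found: {path}")
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise DataError(f"no .tsv time-series files in {path}")
    panel = {}
    region_ids = None
    for f in files:
        ts = pd.read_csv(f, sep="\t")
        if region_ids is None:
            region_ids = list(ts.columns)
        elif list(ts.columns) != region_ids:
            raise DataError(f"region columns in {f.name} differ from first subject")
        panel[f.stem] = ts
    return pd.Series(panel)
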