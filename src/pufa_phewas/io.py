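"""Tab-delimited table I/O with header validation.

Every table the pipeline reads or writes is plain tab-delimited text with a
header row.  Readers validate required columns and raise column-level
diagnostics; ``write_* / read_*`` round-trip to float-text precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

__all__ = ["read_table", "write_table", "read_cohort", "write_cohort",
           "read_summary_stats", "write_summary_stats", "read_weights",
           "read_group_map", "write_group_map"]

SUMMARY_STATS_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf",
                         "beta", "se", "p", "n"]
WEIGHTS_COLUMNS = ["snp", "effect_allele", "weight"]
GROUP_MAP_COLUMNS = ["phecode", "group"]
COHORT_REQUIRED = ["id", "age", "sex"]


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited table, checking emptiness and required columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty input file: {path}")
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=COHORT_REQUIRED)


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    return write_table(df, path)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=SUMMARY_STATS_COLUMNS)


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in SUMMARY_STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing column(s) {missing}")
    return write_table(df, path)


def read_weights(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=WEIGHTS_COLUMNS)


def read_group_map(path: str | Path) -> dict[str, str]:
    read_table(path, required=GROUP_MAP_COLUMNS)  # header/emptiness diagnostics
    df = pd.read_csv(path, sep="\t", dtype=str)  # phecodes like "008" stay text
    return dict(zip(df["phecode"], df["group"]))


def write_group_map(group_map: dict[str, str], path: str | Path) -> Path:
    df = pd.DataFrame({"phecode": list(group_map), "group": list(group_map.values())})
    return write_table(df, path)
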