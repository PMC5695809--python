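"""Delimited-text I/O for cohort and cluster tables.

All primary outputs are plain CSV with a commented header naming the tool
version and the resolved seed, so runs can be diffed and reproduced. An
optional loader ingests real patient tables (XLSX or delimited text) with a
user-supplied column-schema map.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from . import __version__
from .config import read_config

COHORT_COLUMNS = [
    "patient_id", "group", "visit", "tsh", "ft4", "ft3", "lt4_dose", "weight",
]


def write_table(df: pd.DataFrame, path: str | os.PathLike, seed: int | None = None,
                meta: dict | None = None) -> None:
    """Write a table as CSV preceded by ``#`` header lines (tool version,
    seed, extra metadata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# mimelog {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (``#`` lines skipped);
    plain headerless-comment CSV/TSV also works."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, comment="#", sep=sep)


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort table and validate the column schema."""
    df = read_table(path)
    missing = [c for c in ("patient_id", "group", "visit", "tsh", "ft4") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing required columns {missing}")
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
    return df[COHORT_COLUMNS]


def load_real_cohort(path: str | os.PathLike, schema_path: str | os.PathLike) -> pd.DataFrame:
    """Ingest a real patient table (XLSX via openpyxl, or CSV/TSV) using a
    ``key = value`` schema file mapping our column names to the file's
    (e.g. ``tsh = TSH_mIU_L``). Only mapped columns are read; the result has
    the standard cohort schema. Absence of such files never breaks anything
    else — this loader is an optional re-analysis path.
    """
    schema = read_config(schema_path)
    unknown = set(schema) - set(COHORT_COLUMNS)
    if unknown:
        raise ValueError(f"schema maps unknown columns {sorted(unknown)}")
    suffix = Path(path).suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep="\t" if suffix in (".tsv", ".tab") else ",", comment="#")
    missing_src = [src for src in schema.values() if src not in raw.columns]
    if missing_src:
        raise ValueError(f"source file lacks mapped columns {missing_src}")
    df = pd.DataFrame({ours: raw[theirs] for ours, theirs in schema.items()})
    if "patient_id" not in df.columns:
        df["patient_id"] = [f"p{i:05d}" for i in range(len(df))]
    if "visit" not in df.columns:
        df["visit"] = 1
    if "group" not in df.columns:
        df["group"] = "control"
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
    return df[COHORT_COLUMNS]
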