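"""Readers/writers for the delimited-text tables and JSON run summaries.

All tables are tab-separated with a mandatory header row; numeric columns
use the period as decimal separator regardless of locale.  Units live in
the column names (ppm, kHz, degrees); residue and carbon indices are
1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class TableError(ValueError):
    """A delimited-text table failed schema validation."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict  # column name -> dtype ("int", "float", "str")
    key: tuple     # column names whose combinations must be unique


RESTRAINTS_SCHEMA = TableSchema(
    name="restraints",
    columns={"residue_index": "int", "shift_ppm": "float", "error_ppm": "float"},
    key=("residue_index",))

SHIFTS_SCHEMA = TableSchema(
    name="shifts",
    columns={"residue_index": "int", "residue_type": "str",
             "atom": "str", "shift_ppm": "float"},
    key=("residue_index", "atom"))

PRE_SCHEMA = TableSchema(
    name="pre",
    columns={"residue_index": "int", "intensity_ref": "float",
             "intensity_para": "float", "noise_ref": "float",
             "noise_para": "float"},
    key=("residue_index",))

SPLITTINGS_SCHEMA = TableSchema(
    name="splittings",
    columns={"carbon_index": "int", "group": "str", "splitting_khz": "float",
             "condition": "str", "lipid": "str"},
    key=("carbon_index", "condition"))


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a TSV table against ``schema``.

    Raises :class:`TableError` naming the file, missing columns, bad cells
    (with 1-based data row numbers) or duplicate keys.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: file not found")
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in schema.columns if c not in raw.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing} "
                         f"for {schema.name} table")
    out = pd.DataFrame(index=raw.index)
    for col, kind in schema.columns.items():
        if kind == "str":
            out[col] = raw[col].astype(str).str.strip()
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            rows = (raw.index[bad | raw[col].isna()] + 2).tolist()  # +2: header+1-based
            raise TableError(f"{path}: non-numeric or empty {col!r} "
                             f"at file line(s) {rows}")
        out[col] = vals.astype(int if kind == "int" else float)
    if schema.key:
        dup = out.duplicated(subset=list(schema.key))
        if dup.any():
            keys = out.loc[dup, list(schema.key)].values.tolist()
            raise TableError(f"{path}: duplicate {schema.key} entries {keys}")
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as TSV with header; floats with full precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_summary(summary: dict, path) -> None:
    """JSON run summary with full parameter provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
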