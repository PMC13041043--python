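"""Validated CSV/TSV readers and writers.

Delimiter is chosen from the file extension (.csv -> comma, anything else
-> tab).  Schemas declare required and optional columns with their dtypes;
missing values are preserved as missing.  Floats are serialized with six
significant digits, so numeric round trips are exact to ~1e-6 relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableSchema",
    "SchemaError",
    "read_table",
    "write_table",
    "CTD_SCHEMA",
    "NUTRIENT_SCHEMA",
    "META_SCHEMA",
    "TAXONOMY_SCHEMA",
    "GENECOUNT_SCHEMA",
]

FLOAT_FORMAT = "%.6g"


class SchemaError(ValueError):
    """A table does not satisfy its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: dict[str, type] = field(default_factory=dict)
    optional: dict[str, type] = field(default_factory=dict)

    def columns(self) -> dict[str, type]:
        return {**self.required, **self.optional}


CTD_SCHEMA = TableSchema(
    "ctd",
    required={"station_id": str, "region": str, "year": int,
              "depth_m": float, "temp_c": float, "sal": float},
    optional={"sigma_theta": float, "water_mass": str},
)

NUTRIENT_SCHEMA = TableSchema(
    "nutrients",
    required={"station_id": str, "region": str, "year": int,
              "depth_m": float},
    optional={"sal": float, "ammonium": float, "nitrate_nitrite": float,
              "nitrite": float, "phosphate": float, "silicic_acid": float,
              "chl_a": float, "water_mass": str},
)

META_SCHEMA = TableSchema(
    "sample_meta",
    required={"sample_id": str, "region": str, "year": int,
              "depth_m": float, "water_mass": str},
)

TAXONOMY_SCHEMA = TableSchema(
    "taxonomy",
    required={"asv_id": str, "domain": str},
    optional={"phylum": str, "class": str, "order": str,
              "family": str, "genus": str},
)

GENECOUNT_SCHEMA = TableSchema(
    "gene_counts",
    required={"sample_id": str, "gene_symbol": str,
              "mapped_reads": int, "gene_length_bp": int},
    optional={"contig_id": str},
)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_table(path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a CSV/TSV table, validating against a schema if given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # only empty cells are missing; tokens like "n/a" are parse errors
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False, na_values=[""])
    if schema is None:
        return df
    for col in schema.required:
        if col not in df.columns:
            raise SchemaError(
                f"{schema.name} table {path} lacks required column {col!r}")
    for col, typ in schema.columns().items():
        if col not in df.columns:
            continue
        if typ in (float, int):
            try:
                converted = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                bad = pd.to_numeric(df[col], errors="coerce")
                rows = df.index[bad.isna() & df[col].notna()].tolist()
                raise SchemaError(
                    f"{schema.name} table {path}: column {col!r} has "
                    f"unparseable numeric values at row(s) {rows[:5]}")
            if typ is int and converted.notna().all():
                converted = converted.astype(int)
            df[col] = converted
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table; round-trips through read_table for all schemas."""
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False,
              float_format=FLOAT_FORMAT)
    return path
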