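"""Gene-count tables and protein-domain interval tables.

Count tables are pandas DataFrames (rows = families, columns = species,
non-negative integers).  The completeness filter implements the rule used
for turnover analyses: a species is retained only if it carries at least
one gene in every subclade table supplied.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_count_table",
    "validate_count_table",
    "filter_complete_species",
    "read_domain_table",
    "validate_domain_table",
]


def _as_buffer(source):
    if hasattr(source, "read"):
        return source
    text = str(source)
    if os.path.exists(text):
        return text
    if "\t" in text or "\n" in text:
        return io.StringIO(text)
    raise ValueError("source must be TSV text, a path, or a file handle")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    arr = table.to_numpy()
    if arr.size == 0:
        raise ValueError("empty count table")
    if not np.issubdtype(arr.dtype, np.integer):
        flo = table.to_numpy(dtype=float)
        if np.any(~np.isfinite(flo)) or np.any(flo != np.round(flo)):
            raise ValueError("count table cells must be integers")
        table = table.astype(int)
    if (table.to_numpy() < 0).any():
        raise ValueError("count table cells must be >= 0")
    return table


def read_count_table(source) -> pd.DataFrame:
    """Read a families x species TSV of non-negative integer gene counts."""
    df = pd.read_csv(_as_buffer(source), sep="\t", index_col=0)
    return validate_count_table(df)


def filter_complete_species(
    table: pd.DataFrame, subclade_tables: Iterable[pd.DataFrame] | Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Restrict ``table`` to species with >= 1 gene in every subclade table.

    Column (species) order is preserved.  Filtering is idempotent: applying
    it again with the same subclade tables returns an identical table.
    """
    if isinstance(subclade_tables, Mapping):
        subclade_tables = list(subclade_tables.values())
    tables = list(subclade_tables)
    if not tables:
        raise ValueError("at least one subclade table is required")
    keep = [
        sp
        for sp in table.columns
        if all(sp in t.columns and int(t[sp].sum()) >= 1 for t in tables)
    ]
    return table.loc[:, keep]


def validate_domain_table(df: pd.DataFrame, protein_length: int | None = None) -> pd.DataFrame:
    required = {"domain", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"domain table needs columns {sorted(required)}")
    df = df.copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 1).any() or (df["start"] > df["end"]).any():
        raise ValueError("domain intervals must satisfy 1 <= start <= end")
    if protein_length is not None and (df["end"] > protein_length).any():
        raise ValueError("domain interval exceeds protein length")
    ordered = df.sort_values("start")
    if (ordered["start"].to_numpy()[1:] <= ordered["end"].to_numpy()[:-1]).any():
        raise ValueError("domain intervals may not overlap")
    return df


def read_domain_table(source, protein_length: int | None = None) -> pd.DataFrame:
    """Read a domain interval TSV (columns: domain, start, end; 1-based inclusive)."""
    df = pd.read_csv(_as_buffer(source), sep="\t")
    return validate_domain_table(df, protein_length)
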