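"""Delimited-table I/O: twist-angle time series and salt-bridge occupancy tables.

Two small occupancy tables are bundled with the package
(``knob_groove_salt_bridges`` and ``lasso_linker_salt_bridges``): published
occupancy percentages of salt bridges between FH2 domains of the formins
Cdc12, Bni1 and mDia1 and actin subunits, used by the bridge-counting
analyses and the worked examples.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def read_series_table(path, columns=None) -> pd.DataFrame:
    """Read a whitespace- and/or comma-delimited numeric time-series table.

    The first column is interpreted as time; remaining columns are values
    (twist angles in degrees in the bundled workflows).  A header line of
    column names is honored if present.  Non-numeric cells raise ValueError
    naming the offending row.
    """
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    # if the "header" was actually numeric data, re-read headerless
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#", header=None)
        df.columns = ["time"] + [f"value{i}" for i in range(1, df.shape[1])]
    except ValueError:
        pass
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric cell in column {col!r} at row {bad}")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise KeyError(f"requested columns not in table: {missing}")
        df = df[list(columns)]
    return df


def write_series_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


_BUNDLED = {
    "knob_groove_salt_bridges": "knob_groove_salt_bridges.tsv",
    "lasso_linker_salt_bridges": "lasso_linker_salt_bridges.tsv",
}


def load_salt_bridge_table(name_or_path) -> pd.DataFrame:
    """Load a salt-bridge occupancy table (bundled name or file path).

    Columns: ``formin, fh2_residue, fh2_domain, actin_residue,
    actin_subunit`` plus one or more occupancy columns in percent
    (missing entries are NA: the bridge was not observed in that window).
    """
    if name_or_path in _BUNDLED:
        ref = resources.files("formincg") / "data" / _BUNDLED[name_or_path]
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(name_or_path, sep="\t")
    occ_cols = [c for c in df.columns if c.startswith("occupancy")]
    for c in occ_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
        vals = df[c].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"occupancy column {c!r} outside [0, 100]")
    return df


def count_bridges(table: pd.DataFrame, formin: str | None = None,
                  occupancy_column: str | None = None,
                  min_occupancy: float = 0.0,
                  domain: str | None = None) -> int:
    """Count distinct salt bridges passing an occupancy filter.

    A bridge is a distinct (FH2 residue, FH2 domain, actin residue, actin
    subunit) row.  Rows pass when occupancy > 0 and occupancy >=
    ``min_occupancy`` (so the default counts every observed bridge).
    """
    df = table
    if formin is not None:
        df = df[df["formin"].str.lower() == formin.lower()]
    if domain is not None:
        df = df[df["fh2_domain"].str.startswith(domain)]
    if occupancy_column is None:
        occ_cols = [c for c in df.columns if c.startswith("occupancy")]
        if len(occ_cols) != 1:
            raise ValueError(f"ambiguous occupancy column; specify one of {occ_cols}")
        occupancy_column = occ_cols[0]
    occ = df[occupancy_column]
    passing = df[(occ > 0) & (occ >= min_occupancy)]
    keys = ["fh2_residue", "fh2_domain", "actin_residue", "actin_subunit"]
    return int(passing[keys].drop_duplicates().shape[0])
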