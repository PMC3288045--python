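"""Readers and writers for the pipeline's table dialects.

All tables are plain CSV/TSV.  Writers prepend a ``#`` comment line carrying
the resolved-config hash so every output file is traceable to the run that
produced it; readers skip comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingColumnError, TableFormatError

PER_CELL_COLUMNS = ["plate_id", "well", "cell_id",
                    "ch_dna", "ch_marker", "ch_gfp_nuc", "ch_gfp_cyto"]
PLATE_MAP_COLUMNS = ["plate_id", "well", "role", "target_id", "oligo_id",
                     "treatment_gy", "replicate"]
WELL_SUMMARY_COLUMNS = ["plate_id", "well", "metric", "n_cells",
                        "pos_fraction", "flag"]
OBSERVATION_COLUMNS = ["target", "co_kd", "dose_gy", "bio_rep", "tech_rep",
                       "value", "assay"]
TARGET_SUMMARY_COLUMNS = ["target", "average", "sd", "zscore"]


def write_table(df: pd.DataFrame, path: str | Path,
                config_hash: str | None = None, sep: str = ",") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=False, sep=sep)


def _read_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required column(s) {missing}")


def read_per_cell_table(path: str | Path) -> pd.DataFrame:
    """Typed per-cell records from CSV.

    GFP columns may be entirely empty (reporter absent).  Rows whose marker
    and DNA intensities are both unparseable are dropped; their count is
    reported in ``df.attrs['n_malformed']``.  Unknown columns are preserved.
    """
    df = _read_csv(path)
    required = ["plate_id", "well", "cell_id", "ch_dna", "ch_marker"]
    _require_columns(df, required, path)
    for col in ("ch_dna", "ch_marker", "ch_gfp_nuc", "ch_gfp_cyto"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    malformed = df["ch_dna"].isna() & df["ch_marker"].isna() & \
        df["ch_gfp_nuc"].isna() & df["ch_gfp_cyto"].isna()
    out = df.loc[~malformed].reset_index(drop=True)
    out.attrs["n_malformed"] = int(malformed.sum())
    return out


def read_plate_map(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, PLATE_MAP_COLUMNS, path)
    df["treatment_gy"] = pd.to_numeric(df["treatment_gy"], errors="raise")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    df["target_id"] = df["target_id"].fillna("")
    df["oligo_id"] = df["oligo_id"].fillna("")
    return df


def read_well_summaries(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, WELL_SUMMARY_COLUMNS, path)
    df["n_cells"] = pd.to_numeric(df["n_cells"], errors="raise").astype(int)
    df["pos_fraction"] = pd.to_numeric(df["pos_fraction"], errors="raise")
    df["flag"] = df["flag"].astype(bool)
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, OBSERVATION_COLUMNS, path)
    for col in ("dose_gy", "value"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("bio_rep", "tech_rep"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return df


def read_target_summary_table(path: str | Path) -> pd.DataFrame:
    """Per-target screen statistics in the standard summary layout
    (``target, average, sd, zscore``).

    Rejects duplicate gene symbols and reports the (1-based) row number of
    any non-numeric field; an empty table is an error.
    """
    df = _read_csv(path)
    _require_columns(df, TARGET_SUMMARY_COLUMNS, path)
    if df.empty:
        raise TableFormatError(f"{path}: no target rows")
    dup = df["target"].duplicated()
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicate target symbol(s) {sorted(df.loc[dup, 'target'].unique())}")
    for col in ("average", "sd", "zscore"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0]) + 1
            raise TableFormatError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = coerced
    return df.reset_index(drop=True)


def write_target_summary_table(table: pd.DataFrame, path: str | Path,
                               config_hash: str | None = None) -> None:
    """Export a screen table in the standard per-target summary layout."""
    out = pd.DataFrame({
        "target": table["target_id"],
        "average": table["mean_pos"],
        "sd": table["sd_pos"],
        "zscore": table["z_score"],
    })
    write_table(out, path, config_hash=config_hash)


def write_newick(newick: str, path: str | Path,
                 config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        fh.write(newick.rstrip() + "\n")
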