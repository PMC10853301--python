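"""Reading, validating and writing basin / subbasin tables and rankings.

Canonical interchange format is CSV.  A basin table has one row per
HUC04-sized candidate basin; a subbasin table has one row per HUC08
subbasin with a ``basin_id`` foreign key into the basin table.  Identifier
columns are opaque strings; region ids carry no required numbering.

Column schemas (see ``BASIN_COLUMNS`` / ``SUBBASIN_COLUMNS``):

basins.csv
    basin_id, region_id, area_km2, pop_served_per_km2, pct_waterbodies,
    biotic_index, delivered_N_yield, delivered_P_yield

subbasins.csv
    huc08_id, basin_id, stream_N_vwm, stream_P_vwm, fertmanure_N,
    fertmanure_P, wwtp_N, wwtp_P, septic_N, tile_fraction, runoff,
    gw_shallow_no3, gw_ps_no3, resid_N, resid_P

Concentrations are mg/L, yields kg/km2/yr, runoff m/yr, tile_fraction a
fraction of HUC08 area, residuals signed percent errors of predicted loads
in log space.  Missing values are permitted (NaN) and are renormalized out
of category scores downstream; negative concentrations or yields are not.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ReferentialError, SchemaError, TableValidationError

log = logging.getLogger("basinrank")

__all__ = [
    "BASIN_COLUMNS",
    "SUBBASIN_COLUMNS",
    "load_tables",
    "validate_tables",
    "write_rankings",
    "import_workbook_sheet",
]

BASIN_COLUMNS = (
    "basin_id",
    "region_id",
    "area_km2",
    "pop_served_per_km2",
    "pct_waterbodies",
    "biotic_index",
    "delivered_N_yield",
    "delivered_P_yield",
)

SUBBASIN_COLUMNS = (
    "huc08_id",
    "basin_id",
    "stream_N_vwm",
    "stream_P_vwm",
    "fertmanure_N",
    "fertmanure_P",
    "wwtp_N",
    "wwtp_P",
    "septic_N",
    "tile_fraction",
    "runoff",
    "gw_shallow_no3",
    "gw_ps_no3",
    "resid_N",
    "resid_P",
)

#: Columns that must be >= 0 wherever present.
_NONNEGATIVE_SUBBASIN = (
    "stream_N_vwm",
    "stream_P_vwm",
    "fertmanure_N",
    "fertmanure_P",
    "wwtp_N",
    "wwtp_P",
    "septic_N",
    "runoff",
    "gw_shallow_no3",
    "gw_ps_no3",
)
_NONNEGATIVE_BASIN = ("pop_served_per_km2", "delivered_N_yield", "delivered_P_yield")


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {missing}")


def _check_bounds(df, column, lo, hi, table):
    s = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[s.notna() & ((s < lo) | (s > hi))]
    if len(bad):
        row = int(bad[0])
        raise TableValidationError(
            f"{table} row {row}: {column}={df.loc[row, column]!r} outside [{lo}, {hi}]"
        )


def _check_nonnegative(df, columns, table):
    for column in columns:
        s = pd.to_numeric(df[column], errors="coerce")
        bad = df.index[s.notna() & (s < 0)]
        if len(bad):
            row = int(bad[0])
            raise TableValidationError(
                f"{table} row {row}: {column}={df.loc[row, column]!r} must be >= 0"
            )


def validate_tables(basins: pd.DataFrame, subbasins: pd.DataFrame) -> None:
    """Check both tables against the schema invariants; raise on violation."""
    _require_columns(basins, BASIN_COLUMNS, "basin")
    _require_columns(subbasins, SUBBASIN_COLUMNS, "subbasin")

    if basins["basin_id"].duplicated().any():
        dupes = basins.loc[basins["basin_id"].duplicated(), "basin_id"].tolist()
        raise TableValidationError(f"duplicate basin_id(s): {dupes}")
    if subbasins["huc08_id"].duplicated().any():
        dupes = subbasins.loc[subbasins["huc08_id"].duplicated(), "huc08_id"].tolist()
        raise TableValidationError(f"duplicate huc08_id(s): {dupes}")

    area = pd.to_numeric(basins["area_km2"], errors="coerce")
    bad = basins.index[~(area > 0)]
    if len(bad):
        row = int(bad[0])
        raise TableValidationError(
            f"basin row {row}: area_km2={basins.loc[row, 'area_km2']!r} must be > 0"
        )
    _check_bounds(basins, "biotic_index", 0.0, 1.0, "basin")
    _check_bounds(basins, "pct_waterbodies", 0.0, 100.0, "basin")
    _check_nonnegative(basins, _NONNEGATIVE_BASIN, "basin")

    _check_bounds(subbasins, "tile_fraction", 0.0, 1.0, "subbasin")
    _check_nonnegative(subbasins, _NONNEGATIVE_SUBBASIN, "subbasin")

    orphans = set(subbasins["basin_id"]) - set(basins["basin_id"])
    if orphans:
        raise ReferentialError(
            f"subbasin(s) reference unknown basin_id(s): {sorted(orphans)}"
        )


def _read_csv(path, aliases: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"basin_id": str, "region_id": str, "huc08_id": str})
    if aliases:
        df = df.rename(columns=dict(aliases))
    return df


def load_tables(
    basin_path,
    subbasin_path,
    aliases: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the basin and subbasin CSV tables.

    ``aliases`` optionally maps column names found in the files to the
    canonical schema names (for importing tables whose headers differ, e.g.
    sheets converted from a spreadsheet workbook).
    """
    basins = _read_csv(basin_path, aliases)
    subbasins = _read_csv(subbasin_path, aliases)
    validate_tables(basins, subbasins)
    log.info(
        "loaded %d basins in %d regions, %d subbasins",
        len(basins), basins["region_id"].nunique(), len(subbasins),
    )
    return basins, subbasins


def import_workbook_sheet(
    workbook_path,
    sheet_name,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read one sheet of a spreadsheet workbook into a DataFrame.

    A thin converter for spreadsheet data releases: rename columns via
    ``aliases`` and write the result with ``DataFrame.to_csv`` to obtain the
    canonical CSV schema.
    """
    df = pd.read_excel(workbook_path, sheet_name=sheet_name)
    if aliases:
        df = df.rename(columns=dict(aliases))
    for col in ("basin_id", "region_id", "huc08_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def write_rankings(results: pd.DataFrame, path) -> None:
    """Write a ranking-result table to CSV.

    One row per basin, ordered by national ordinal then basin_id; repeated
    calls on identical input produce byte-identical files.
    """
    if results is None or len(results) == 0:
        raise TableValidationError("refusing to write an empty ranking table")
    if results["basin_id"].duplicated().any():
        dupes = results.loc[results["basin_id"].duplicated(), "basin_id"].tolist()
        raise TableValidationError(f"duplicate basin_id(s) in results: {dupes}")
    out = results.sort_values(
        ["national_ordinal", "basin_id"], kind="mergesort"
    ).reset_index(drop=True)
    out.to_csv(path, index=False, lineterminator="\n")
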