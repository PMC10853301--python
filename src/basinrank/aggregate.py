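"""Collapsing HUC08 subbasin values to one value per candidate basin.

Summary statistics follow the inclusive linear-interpolation percentile
convention (for sorted values v1..vn and fraction p, position
h = 1 + p*(n-1), interpolating between the bracketing order statistics) so
that p=0 and p=1 reproduce the minimum and maximum exactly.  Interquartile
ranges (p75 - p25) are used instead of full ranges to damp outliers.

Stream nutrient concentrations can be base-10 log transformed before
aggregation; zeros are floored at half the smallest positive value of the
basin's multiset so every subbasin stays rankable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RankingConfig, VariableSpec
from .exceptions import ConfigError, DomainError, TableValidationError

log = logging.getLogger("basinrank")

__all__ = [
    "percentile",
    "log10_floored",
    "aggregate_variable",
    "delivered_yield",
    "BasinVariableTable",
    "build_basin_table",
]


def _as_clean_array(values) -> np.ndarray:
    arr = np.asarray(list(values) if not hasattr(values, "__array__") else values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return arr


def percentile(values, p: float) -> float:
    """Inclusive linear-interpolation percentile of a multiset.

    ``p`` is a fraction in [0, 1]; endpoints are the minimum and maximum.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"percentile fraction must be in [0, 1], got {p}")
    arr = _as_clean_array(values)
    if arr.size == 0:
        raise DomainError("percentile of an empty multiset is undefined")
    # np.quantile 'linear' is exactly h = 1 + p*(n-1) on sorted values
    return float(np.quantile(arr, p, method="linear"))


def log10_floored(values):
    """Base-10 logarithm with a half-minimum floor for zeros.

    Positive values map to log10(v); zeros map to log10 of half the smallest
    positive value in the multiset.  An all-zero multiset maps to all zeros
    (with a warning) since no floor is defined.  Negative values are a
    domain error.
    """
    arr = np.asarray(list(values) if not hasattr(values, "__array__") else values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if (finite < 0).any():
        raise DomainError("log10_floored requires non-negative values")
    positive = finite[finite > 0]
    if positive.size == 0:
        if (finite == 0).any():
            log.warning("log10_floored: all-zero multiset left unchanged")
        return np.zeros_like(arr)
    # log10(min/2) written as a difference so tiny minima cannot underflow
    floor = np.log10(positive.min()) - np.log10(2.0)
    out = np.where(arr > 0, np.log10(np.where(arr > 0, arr, 1.0)), floor)
    out[np.isnan(arr)] = np.nan
    return out


def aggregate_variable(sub_values, spec: VariableSpec) -> float:
    """Collapse one basin's subbasin values per the variable spec.

    Supported aggregations: ``median`` (p50), ``iqr_range`` (p75 - p25),
    ``minimum``, ``mean_abs`` (mean of absolute values).  The spec's
    transform is applied to the multiset before aggregation.
    """
    if spec.aggregation not in ("median", "iqr_range", "minimum", "mean_abs"):
        raise ConfigError(
            f"variable {spec.name!r}: aggregation {spec.aggregation!r} is not a "
            "subbasin aggregation"
        )
    arr = _as_clean_array(sub_values)
    if arr.size == 0:
        raise DomainError(f"variable {spec.name!r}: no subbasin values to aggregate")
    if spec.transform == "log10_floored":
        arr = log10_floored(arr)
    if spec.aggregation == "median":
        return percentile(arr, 0.5)
    if spec.aggregation == "iqr_range":
        return percentile(arr, 0.75) - percentile(arr, 0.25)
    if spec.aggregation == "minimum":
        return float(arr.min())
    return float(np.abs(arr).mean())  # mean_abs


def delivered_yield(total_delivered_load: float, area_km2: float) -> float:
    """Delivered load (kg/yr) divided by basin area (km2) -> kg/km2/yr."""
    if not area_km2 > 0:
        raise DomainError(f"area_km2 must be > 0, got {area_km2}")
    return float(total_delivered_load) / float(area_km2)


@dataclass(frozen=True)
class BasinVariableTable:
    """Aggregated basin-level values for every configured variable.

    ``values`` is indexed by basin_id with one column per variable name;
    ``provenance`` records, per (basin, variable), how many subbasin values
    fed the aggregate (0 for basin-level columns taken as-is) and which
    transform was applied.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame


def _basin_level_series(basins: pd.DataFrame, spec: VariableSpec) -> pd.Series:
    if spec.source_column not in basins.columns:
        raise ConfigError(
            f"variable {spec.name!r}: basin table has no column {spec.source_column!r}"
        )
    s = pd.to_numeric(basins[spec.source_column], errors="coerce")
    if spec.aggregation == "sum_over_area":
        s = s / pd.to_numeric(basins["area_km2"], errors="coerce")
    if spec.transform == "log10_floored":
        s = pd.Series(log10_floored(s.to_numpy()), index=s.index)
    return pd.Series(s.to_numpy(), index=basins["basin_id"].to_numpy(), name=spec.name)


def build_basin_table(
    basins: pd.DataFrame,
    subbasins: pd.DataFrame,
    config: RankingConfig,
) -> BasinVariableTable:
    """Derive one basin-level value per configured variable.

    Subbasin-level variables are grouped by ``basin_id`` and collapsed with
    :func:`aggregate_variable`; basin-level variables are read straight from
    the basin table (optionally normalized by area).  Basins with no
    non-missing subbasin value for a variable get NaN there (renormalized
    away downstream) unless ``config.missing_policy`` is ``strict``.
    """
    basin_ids = basins["basin_id"].to_numpy()
    grouped = {
        name: g for name, g in subbasins.groupby("basin_id", sort=False)
    }
    values: dict[str, pd.Series] = {}
    prov_rows = []
    for spec in config.variables:
        if spec.level == "basin":
            values[spec.name] = _basin_level_series(basins, spec)
            for bid in basin_ids:
                prov_rows.append((bid, spec.name, 0, spec.transform))
            continue
        if spec.source_column not in subbasins.columns:
            raise ConfigError(
                f"variable {spec.name!r}: subbasin table has no column "
                f"{spec.source_column!r}"
            )
        col = {}
        for bid in basin_ids:
            g = grouped.get(bid)
            sub = (
                pd.to_numeric(g[spec.source_column], errors="coerce").dropna()
                if g is not None
                else pd.Series(dtype=float)
            )
            n = int(sub.size)
            prov_rows.append((bid, spec.name, n, spec.transform))
            if n == 0:
                if config.missing_policy == "strict":
                    raise TableValidationError(
                        f"basin {bid!r}: no subbasin values for variable {spec.name!r}"
                    )
                log.warning(
                    "basin %s: variable %s has no subbasin values; "
                    "dropped from its category score", bid, spec.name,
                )
                col[bid] = np.nan
                continue
            if n == 1 and spec.aggregation == "iqr_range":
                log.warning(
                    "basin %s: variable %s computed from a single subbasin; "
                    "range degenerates to 0", bid, spec.name,
                )
            col[bid] = aggregate_variable(sub.to_numpy(), spec)
        values[spec.name] = pd.Series(col, name=spec.name)

    table = pd.DataFrame(values).reindex(basin_ids)
    table.index.name = "basin_id"
    provenance = pd.DataFrame(
        prov_rows, columns=["basin_id", "variable", "n_subbasins", "transform"]
    )
    return BasinVariableTable(values=table, provenance=provenance)
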