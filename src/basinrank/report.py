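"""Priority-basin selection, cross-approach comparison, and summaries.

The study design keeps the top two basins per hydrologic region as priority
basins (18 regions x 2 = 36 from a 163-basin roster).  Because the impact
and variability approaches optimize different things, their regional top
picks usually differ; :func:`compare_top_picks` counts the disagreeing
regions.  Distribution summaries replace violin-plot figures with per-region
quantile tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .aggregate import percentile
from .exceptions import DomainError

__all__ = [
    "select_top_n",
    "compare_top_picks",
    "summarize_categories",
    "load_reference_top_basins",
    "reference_top_results",
]


def select_top_n(results: pd.DataFrame, n: int) -> pd.DataFrame:
    """Per region, the ``n`` basins with the smallest region ordinals.

    Returns a priority-set table with columns ``region_id, region_ordinal,
    basin_id, overall, approach``, sorted by region then ordinal.  Regions
    with fewer than ``n`` basins contribute all of them.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if len(results) == 0:
        raise DomainError("empty result collection")
    cols = ["region_id", "region_ordinal", "basin_id", "overall", "approach"]
    out = (
        results.loc[results["region_ordinal"] <= n, cols]
        .sort_values(["region_id", "region_ordinal"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def compare_top_picks(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of regions whose ordinal-1 basin differs between two rankings."""
    tops_a = _top1(a)
    tops_b = _top1(b)
    if set(tops_a.index) != set(tops_b.index):
        raise DomainError(
            "result collections cover different regions: "
            f"{sorted(set(tops_a.index) ^ set(tops_b.index))}"
        )
    return int((tops_a != tops_b.reindex(tops_a.index)).sum())


def _top1(results: pd.DataFrame) -> pd.Series:
    top = results.loc[results["region_ordinal"] == 1, ["region_id", "basin_id"]]
    if top["region_id"].duplicated().any():
        raise DomainError("multiple ordinal-1 basins in one region")
    return top.set_index("region_id")["basin_id"]


def load_reference_top_basins() -> pd.DataFrame:
    """The originally published top-2 regional selections, both approaches.

    Columns: ``region_number, region_name, approach, region_rank,
    basin_name`` — 18 regions x 2 approaches x 2 ranks.  These are the
    study's published per-region priority picks; the full underlying
    variable tables live in its external data release and are not shipped.
    """
    path = resources.files("basinrank") / "data" / "reference_top_basins.csv"
    with path.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def reference_top_results(approach: str) -> pd.DataFrame:
    """Published selections for one approach, as a minimal result table.

    Shapes the reference picks like a ranking-result collection (columns
    ``region_id, basin_id, region_ordinal, approach``) so they can be fed to
    :func:`compare_top_picks` and :func:`select_top_n`.
    """
    ref = load_reference_top_basins()
    sub = ref.loc[ref["approach"] == approach]
    if sub.empty:
        raise DomainError(f"unknown approach {approach!r}")
    return pd.DataFrame(
        {
            "region_id": sub["region_number"].astype(str),
            "basin_id": sub["basin_name"],
            "region_ordinal": sub["region_rank"],
            "approach": approach,
        }
    ).reset_index(drop=True)


def summarize_categories(results: pd.DataFrame) -> pd.DataFrame:
    """Per-region distribution table of category scores.

    One row per region x category with min, p25, median, p75, max
    (inclusive-interpolation quantiles) plus the region's top-ranked basin
    and its score in that category — a tabular stand-in for violin plots.
    """
    if len(results) == 0:
        raise DomainError("empty result collection")
    meta = {
        "basin_id", "region_id", "approach", "scope", "penalized",
        "overall", "region_ordinal", "national_ordinal",
        "region_unit_rank", "national_unit_rank",
    }
    categories = [c for c in results.columns if c not in meta]
    rows = []
    for region, grp in results.groupby("region_id", sort=True):
        top = grp.loc[grp["region_ordinal"] == 1].iloc[0]
        for cat in categories:
            vals = grp[cat].dropna().to_numpy()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "region_id": region,
                    "category": cat,
                    "n_basins": len(grp),
                    "min": percentile(vals, 0.0),
                    "p25": percentile(vals, 0.25),
                    "median": percentile(vals, 0.5),
                    "p75": percentile(vals, 0.75),
                    "max": percentile(vals, 1.0),
                    "top_basin_id": top["basin_id"],
                    "top_basin_score": top[cat],
                }
            )
    return pd.DataFrame(rows)
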