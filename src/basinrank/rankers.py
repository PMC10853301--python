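"""End-to-end ranking pipelines for the impact and variability approaches.

Both are sklearn-style estimators over a ``(basins, subbasins)`` table pair:

* :class:`ImpactRanker` — 14 variables, percent-ranked across the full
  roster, three equally weighted categories (water quality, sources,
  receptors); overall score = WQ + Source + Receptor (max 3.0 under the
  variable-count normalization, with receptors spanning [0, 0.8]).
* :class:`VariabilityRanker` — 20 variables, percent-ranked within each
  hydrologic region (``scope='region'``) or across the roster
  (``scope='national'``), four categories, overall score
  = 1.0*WQ + 1.0*Factor + 0.5*Receptor + 0.5*Accuracy.  At regional scope a
  basin outside its region's top four water-quality scores has 5 points
  subtracted from that score, removing it from contention (the penalty
  exceeds the maximum attainable overall of 3.0).

Ordinal ranks (1 = highest priority) are assigned within each region and
nationally; exact score ties break lexicographically by basin_id so output
is reproducible.  Scoring is fully deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .aggregate import build_basin_table
from .config import RankingConfig, impact_config, variability_config
from .exceptions import ConfigError
from .io import validate_tables
from .scoring import category_score, overall_score, percent_rank

log = logging.getLogger("basinrank")

__all__ = [
    "ImpactRanker",
    "VariabilityRanker",
    "apply_eligibility",
    "run_impact",
    "run_variability",
]


def apply_eligibility(
    category_scores: pd.DataFrame,
    top_k: int = 4,
    penalty: float = 5.0,
) -> pd.DataFrame:
    """Penalize basins outside their region's top-k water-quality scores.

    ``category_scores`` needs columns ``region_id`` and ``water_quality``.
    Within each region, basins whose water-quality score is strictly below
    the k-th highest have ``penalty`` subtracted and ``penalized=True``;
    ties with the k-th score all stay eligible; regions with <= k basins are
    unchanged.  Returns a modified copy.
    """
    out = category_scores.copy()
    out["penalized"] = False
    for region, idx in out.groupby("region_id", sort=False).groups.items():
        wq = out.loc[idx, "water_quality"]
        if wq.notna().sum() <= top_k:
            continue
        threshold = wq.sort_values(ascending=False).iloc[top_k - 1]
        mask = wq < threshold
        if mask.any():
            out.loc[wq.index[mask], "water_quality"] -= penalty
            out.loc[wq.index[mask], "penalized"] = True
            log.info(
                "region %s: %d basin(s) outside the water-quality top %d penalized",
                region, int(mask.sum()), top_k,
            )
    return out


def _ordinals(df: pd.DataFrame, by: str | None) -> pd.Series:
    """1-based priority ordinals on descending overall, ties by basin_id."""
    order = df.sort_values(
        ["overall", "basin_id"], ascending=[False, True], kind="mergesort"
    )
    if by is None:
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    else:
        ranks = order.groupby(by, sort=False).cumcount() + 1
    return ranks.reindex(df.index)


class _BaseRanker(BaseEstimator):
    """Shared fitting machinery; subclasses pin the approach."""

    _approach: str = ""

    def __init__(self, config: RankingConfig | None = None):
        self.config = config

    # -- configuration -----------------------------------------------------
    def _resolved_config(self) -> RankingConfig:
        cfg = self.config
        if cfg is None:
            cfg = impact_config() if self._approach == "impact" else variability_config()
        if cfg.approach != self._approach:
            raise ConfigError(
                f"{type(self).__name__} requires an {self._approach!r} config, "
                f"got {cfg.approach!r}"
            )
        return cfg

    def _rank_scope(self) -> str:
        return "national"

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        """Fit on ``X = (basins, subbasins)`` and compute all rankings.

        Fitted attributes: ``config_``, ``variable_table_`` (aggregated
        basin-level values), ``ranks_`` (per-variable unit ranks),
        ``category_scores_``, ``results_`` (the full ranking table).
        """
        basins, subbasins = X
        validate_tables(basins, subbasins)
        cfg = self._resolved_config()
        self.config_ = cfg

        bvt = build_basin_table(basins, subbasins, cfg)
        self.variable_table_ = bvt
        table = bvt.values  # indexed by basin_id
        region_of = pd.Series(
            basins["region_id"].to_numpy(), index=basins["basin_id"].to_numpy()
        )

        scope = self._rank_scope()
        ranks = {}
        for spec in cfg.variables:
            col = table[spec.name]
            if scope == "national":
                ranks[spec.name] = percent_rank(col, spec.direction)
            else:
                parts = [
                    percent_rank(col.loc[idx], spec.direction)
                    for _, idx in col.groupby(region_of, sort=False).groups.items()
                ]
                ranks[spec.name] = pd.concat(parts).reindex(col.index)
        rank_df = pd.DataFrame(ranks).reindex(table.index)
        self.ranks_ = rank_df

        cats = {}
        for cat in cfg.categories:
            specs = cfg.variables_in(cat)
            cats[cat] = rank_df.apply(
                lambda row: category_score(row, specs, cfg.category_normalization),
                axis=1,
            )
        cat_df = pd.DataFrame(cats).reindex(table.index)
        cat_df.insert(0, "region_id", region_of.reindex(cat_df.index))

        cat_df = self._adjust_categories(cat_df)
        if "penalized" not in cat_df.columns:
            cat_df["penalized"] = False
        self.category_scores_ = cat_df

        score_cols = list(cfg.categories)
        overall = cat_df.apply(
            lambda row: overall_score(row[score_cols], cfg.category_weights), axis=1
        )

        res = cat_df.copy()
        res["overall"] = overall
        res = res.reset_index().rename(columns={"index": "basin_id"})
        res.insert(2, "approach", cfg.approach)
        res.insert(3, "scope", scope)
        res["region_ordinal"] = _ordinals(res, "region_id")
        res["national_ordinal"] = _ordinals(res, None)
        res["region_unit_rank"] = (
            res.groupby("region_id", sort=False)["overall"]
            .transform(lambda s: percent_rank(s, "ascending"))
        )
        res["national_unit_rank"] = percent_rank(res["overall"], "ascending")
        self.results_ = res.reset_index(drop=True)
        return self

    def _adjust_categories(self, cat_df: pd.DataFrame) -> pd.DataFrame:
        return cat_df

    def fit_predict(self, X, y=None) -> pd.DataFrame:
        """Fit and return the ranking-result table."""
        return self.fit(X).results_

    def predict(self, X=None) -> pd.DataFrame:
        """Return the fitted ranking-result table."""
        if not hasattr(self, "results_"):
            raise ConfigError(f"{type(self).__name__} is not fitted")
        return self.results_


class ImpactRanker(_BaseRanker):
    """Rank basins by urgency of nutrient impact (14-variable approach).

    Variable percent ranks are always computed across the full roster, even
    when results are reported per region, so small regional samples do not
    inflate rank differences.
    """

    _approach = "impact"


class VariabilityRanker(_BaseRanker):
    """Rank basins by their value for nutrient-process studies (20 variables).

    Parameters
    ----------
    config : RankingConfig, optional
        Defaults to the shipped 20-variable configuration.
    scope : {"region", "national"}
        Where percent ranks are computed and whether the regional top-4
        water-quality eligibility penalty applies (regional scope only, per
        the config's eligibility rule).
    """

    _approach = "variability"

    def __init__(self, config: RankingConfig | None = None, scope: str = "region"):
        super().__init__(config=config)
        self.scope = scope

    def _rank_scope(self) -> str:
        if self.scope not in ("region", "national"):
            raise ConfigError(f"unknown scope {self.scope!r}")
        return self.scope

    def _adjust_categories(self, cat_df: pd.DataFrame) -> pd.DataFrame:
        elig = self.config_.eligibility
        if elig.enabled and self._rank_scope() == elig.scope:
            return apply_eligibility(cat_df, elig.top_k, elig.penalty)
        return cat_df


def run_impact(
    basins: pd.DataFrame,
    subbasins: pd.DataFrame,
    config: RankingConfig | None = None,
) -> pd.DataFrame:
    """Run the impact pipeline; thin wrapper over :class:`ImpactRanker`."""
    return ImpactRanker(config=config).fit_predict((basins, subbasins))


def run_variability(
    basins: pd.DataFrame,
    subbasins: pd.DataFrame,
    config: RankingConfig | None = None,
    scope: str = "region",
) -> pd.DataFrame:
    """Run the variability pipeline; wrapper over :class:`VariabilityRanker`."""
    return VariabilityRanker(config=config, scope=scope).fit_predict((basins, subbasins))
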