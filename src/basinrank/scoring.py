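"""Percent-rank normalization and weighted score assembly.

The unit-interval rank of a basin for one variable is the spreadsheet
percent-rank of its value within the scoring scope (the full roster, or one
hydrologic region):

    rank(x) = (# values strictly less than x) / (n - 1)

for an ascending variable (larger raw value = more favorable); descending
variables apply the same formula to negated values.  Ties share a rank; a
singleton scope ranks 1.0.  Category scores are weighted sums of variable
ranks divided by a normalizer — the number of variables in the category
(impact convention) or the category's total weight (variability
convention, which pins every category to the 0-1 interval).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import VariableSpec
from .exceptions import ConfigError, DomainError

__all__ = ["percent_rank", "category_score", "overall_score", "PercentRanker"]


def percent_rank(values, direction: str = "ascending") -> pd.Series:
    """Unit-interval percent ranks of a keyed collection of values.

    ``values`` may be a mapping, Series or array; the result is a Series on
    the same keys with ranks in [0, 1].  NaN entries stay NaN and do not
    count toward n.
    """
    s = pd.Series(values, dtype=float)
    finite = s.dropna()
    if not np.isfinite(finite.to_numpy()).all():
        raise DomainError("percent_rank requires finite values")
    if direction not in ("ascending", "descending"):
        raise DomainError(f"unknown direction {direction!r}")
    n = int(finite.size)
    if n == 0:
        raise DomainError("percent_rank of an empty collection is undefined")
    v = s if direction == "ascending" else -s
    if n == 1:
        out = pd.Series(np.nan, index=s.index)
        out[finite.index] = 1.0
        return out
    # rank(method='min') - 1 == count of values strictly less, ties shared
    return (v.rank(method="min") - 1.0) / (n - 1.0)


def category_score(
    ranks: Mapping[str, float],
    specs: Sequence[VariableSpec],
    normalization: str = "by_variable_count",
) -> float:
    """Weighted rank sum of one category, divided by its normalizer.

    Variables whose rank is missing (NaN) are dropped and the normalizer
    shrinks accordingly (one count, or the variable's weight), so a data gap
    is not scored as "least impacted".
    """
    if len(specs) == 0:
        raise ConfigError("category_score of an empty category is undefined")
    if normalization not in ("by_variable_count", "by_weight_sum"):
        raise ConfigError(f"unknown normalization {normalization!r}")
    total = 0.0
    n_present = 0
    weight_present = 0.0
    for spec in specs:
        r = ranks.get(spec.name, np.nan) if hasattr(ranks, "get") else ranks[spec.name]
        if r is None or (isinstance(r, float) and np.isnan(r)):
            continue
        total += spec.weight * float(r)
        n_present += 1
        weight_present += spec.weight
    if n_present == 0:
        return float("nan")
    denom = n_present if normalization == "by_variable_count" else weight_present
    return total / denom


def overall_score(
    category_scores: Mapping[str, float],
    category_weights: Mapping[str, float],
) -> float:
    """Weighted sum of category scores."""
    for cat in category_weights:
        if cat not in category_scores:
            raise ConfigError(f"weight given for absent category {cat!r}")
    return float(
        sum(w * float(category_scores[c]) for c, w in category_weights.items())
    )


class PercentRanker(BaseEstimator, TransformerMixin):
    """Column-wise percent-rank transformer over a DataFrame.

    ``fit`` stores each column's roster values as the ranking reference;
    ``transform`` maps values to (count of reference values strictly less)
    / (n_ref - 1), so transforming the fitted frame itself reproduces
    :func:`percent_rank` exactly.  Composes with sklearn pipelines.

    Parameters
    ----------
    directions : mapping or str, default "ascending"
        Per-column direction, or one direction for all columns.
    """

    def __init__(self, directions="ascending"):
        self.directions = directions

    def _direction(self, column: str) -> str:
        if isinstance(self.directions, str):
            return self.directions
        return self.directions.get(column, "ascending")

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.reference_ = {}
        for col in X.columns:
            vals = pd.to_numeric(X[col], errors="coerce").dropna().to_numpy()
            if vals.size == 0:
                raise DomainError(f"column {col!r} has no finite values to rank against")
            if not np.isfinite(vals).all():
                raise DomainError(f"column {col!r} contains non-finite values")
            sign = 1.0 if self._direction(col) == "ascending" else -1.0
            self.reference_[col] = np.sort(sign * vals)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            raise DomainError("PercentRanker is not fitted")
        X = pd.DataFrame(X)
        out = {}
        for col in self.feature_names_in_:
            ref = self.reference_[col]
            n = ref.size
            sign = 1.0 if self._direction(col) == "ascending" else -1.0
            v = sign * pd.to_numeric(X[col], errors="coerce").to_numpy(dtype=float)
            if n == 1:
                ranks = np.where(np.isnan(v), np.nan, 1.0)
            else:
                # clip so values beyond the fitted reference saturate at 0/1
                ranks = np.clip(
                    np.searchsorted(ref, v, side="left") / (n - 1.0), 0.0, 1.0
                )
                ranks = np.where(np.isnan(v), np.nan, ranks)
            out[col] = ranks
        return pd.DataFrame(out, index=X.index)
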