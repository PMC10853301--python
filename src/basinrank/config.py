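"""Variable specifications and ranking configurations.

A ranking approach is described by an ordered list of :class:`VariableSpec`
(what to measure, how to collapse HUC08 subbasin values to one basin value,
which direction counts as "more favorable", and the weighting factor), plus
category-level weights and an optional top-k eligibility rule.

Two configurations ship with the package:

``impact``
    14 variables in three categories (water quality, sources, receptors),
    ranking basins by the urgency of nutrient problems.  Category scores are
    weighted rank sums divided by the number of variables in the category.

``variability``
    20 variables in four categories (water quality, factors, accuracy,
    receptors), ranking basins by how much a nutrient-process study could
    learn there.  Category scores are divided by the category's total weight
    so each lands on the 0-1 scale, and overall scoring down-weights the
    receptor and model-accuracy categories by 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .exceptions import ConfigError

__all__ = [
    "CATEGORIES",
    "AGGREGATIONS",
    "VariableSpec",
    "EligibilityRule",
    "RankingConfig",
    "load_config",
    "impact_config",
    "variability_config",
]

CATEGORIES = ("water_quality", "source", "factor", "receptor", "accuracy")
AGGREGATIONS = ("median", "iqr_range", "minimum", "mean_abs", "sum_over_area", "none")
TRANSFORMS = ("none", "log10_floored")
DIRECTIONS = ("ascending", "descending")
LEVELS = ("basin", "subbasin")

#: Required variable counts per approach.
_EXPECTED_N_VARIABLES = {"impact": 14, "variability": 20}


@dataclass(frozen=True)
class VariableSpec:
    """One scored variable.

    Parameters
    ----------
    name : str
        Identifier of the derived basin-level variable (unique per config).
    category : str
        One of ``water_quality``, ``source``, ``factor``, ``receptor``,
        ``accuracy``.
    source_column : str
        Column in the basin table (``level='basin'``) or subbasin table
        (``level='subbasin'``) the value is read from.
    level : str
        ``basin`` or ``subbasin``.
    aggregation : str
        How subbasin values are collapsed (``median``, ``iqr_range``,
        ``minimum``, ``mean_abs``) or, for basin-level columns, ``none`` /
        ``sum_over_area``.
    transform : str
        ``none`` or ``log10_floored`` (base-10 log with a half-minimum floor
        for zeros), applied to each subbasin value before aggregation.
    direction : str
        ``ascending`` means a larger raw value is more favorable (gets the
        higher percent rank); ``descending`` the opposite.
    weight : float
        Strictly positive weighting factor within the category.
    """

    name: str
    category: str
    source_column: str
    level: str
    aggregation: str
    transform: str = "none"
    direction: str = "ascending"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"variable {self.name!r}: unknown category {self.category!r}")
        if self.level not in LEVELS:
            raise ConfigError(f"variable {self.name!r}: unknown level {self.level!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ConfigError(
                f"variable {self.name!r}: unknown aggregation {self.aggregation!r}"
            )
        if self.transform not in TRANSFORMS:
            raise ConfigError(f"variable {self.name!r}: unknown transform {self.transform!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"variable {self.name!r}: unknown direction {self.direction!r}")
        if not self.weight > 0:
            raise ConfigError(f"variable {self.name!r}: weight must be > 0, got {self.weight}")
        if self.level == "subbasin" and self.aggregation in ("none", "sum_over_area"):
            raise ConfigError(
                f"variable {self.name!r}: subbasin-level specs need a subbasin "
                f"aggregation, not {self.aggregation!r}"
            )
        if self.level == "basin" and self.aggregation not in ("none", "sum_over_area"):
            raise ConfigError(
                f"variable {self.name!r}: basin-level specs use aggregation "
                f"'none' or 'sum_over_area', not {self.aggregation!r}"
            )


@dataclass(frozen=True)
class EligibilityRule:
    """Top-k water-quality eligibility gate (variability approach only).

    Basins whose water-quality category score falls strictly below the
    ``top_k``-th highest score in their hydrologic region have ``penalty``
    subtracted from that score, which effectively removes them from the
    regional competition (the penalty exceeds the maximum attainable
    overall score).  Ties with the k-th score stay eligible.
    """

    enabled: bool = False
    top_k: int = 4
    penalty: float = 5.0
    scope: str = "region"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigError(f"eligibility top_k must be >= 1, got {self.top_k}")
        if self.penalty <= 0:
            raise ConfigError(f"eligibility penalty must be > 0, got {self.penalty}")


@dataclass(frozen=True)
class RankingConfig:
    """Full configuration of one ranking approach."""

    approach: str
    variables: tuple[VariableSpec, ...]
    category_weights: Mapping[str, float]
    category_normalization: str = "by_variable_count"
    eligibility: EligibilityRule = field(default_factory=EligibilityRule)
    missing_policy: str = "renormalize"

    def __post_init__(self) -> None:
        if self.approach not in ("impact", "variability"):
            raise ConfigError(f"unknown approach {self.approach!r}")
        expected = _EXPECTED_N_VARIABLES[self.approach]
        if len(self.variables) != expected:
            raise ConfigError(
                f"{self.approach} config must have exactly {expected} variables, "
                f"got {len(self.variables)}"
            )
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigError("variable names must be unique")
        if self.category_normalization not in ("by_variable_count", "by_weight_sum"):
            raise ConfigError(
                f"unknown category_normalization {self.category_normalization!r}"
            )
        if self.missing_policy not in ("renormalize", "strict"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")
        if self.eligibility.enabled and self.approach != "variability":
            raise ConfigError("eligibility gate is only defined for the variability approach")
        present = self.categories
        for cat in self.category_weights:
            if cat not in present:
                raise ConfigError(
                    f"category weight given for {cat!r}, which has no variables"
                )
        for cat in present:
            if cat not in self.category_weights:
                raise ConfigError(f"missing category weight for {cat!r}")

    @property
    def categories(self) -> tuple[str, ...]:
        """Categories actually used, in canonical order."""
        used = {v.category for v in self.variables}
        return tuple(c for c in CATEGORIES if c in used)

    def variables_in(self, category: str) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.category == category)

    def with_(self, **kwargs) -> "RankingConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Loading


def _parse_variable(entry: Mapping) -> VariableSpec:
    try:
        return VariableSpec(**entry)
    except TypeError as exc:
        raise ConfigError(f"bad variable entry {entry!r}: {exc}") from exc


def _parse_config(doc: Mapping, approach: str) -> RankingConfig:
    if not isinstance(doc, Mapping):
        raise ConfigError("config document must be a mapping")
    if doc.get("approach") != approach:
        raise ConfigError(
            f"config declares approach {doc.get('approach')!r}, expected {approach!r}"
        )
    variables = tuple(_parse_variable(v) for v in doc.get("variables", ()))
    elig = EligibilityRule(**doc.get("eligibility", {}))
    return RankingConfig(
        approach=approach,
        variables=variables,
        category_weights=dict(doc.get("category_weights", {})),
        category_normalization=doc.get("category_normalization", "by_variable_count"),
        eligibility=elig,
        missing_policy=doc.get("missing_policy", "renormalize"),
    )


def load_config(path=None, approach: str = "impact") -> RankingConfig:
    """Load a ranking configuration.

    With ``path=None`` the packaged default for ``approach`` is returned;
    otherwise ``path`` must point to a YAML document with the same layout as
    the shipped configs (see ``basinrank/configs/``).
    """
    if approach not in _EXPECTED_N_VARIABLES:
        raise ConfigError(f"unknown approach {approach!r}")
    if path is None:
        text = (
            resources.files("basinrank") / "configs" / f"{approach}.yaml"
        ).read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _parse_config(yaml.safe_load(text), approach)


def impact_config() -> RankingConfig:
    """The default 14-variable impact configuration."""
    return load_config(approach="impact")


def variability_config() -> RankingConfig:
    """The default 20-variable variability configuration."""
    return load_config(approach="variability")
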