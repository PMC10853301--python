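"""End-to-end impact and variability pipelines."""

import numpy as np
import pandas as pd
import pytest

from basinrank import (
    ImpactRanker,
    SyntheticConfig,
    VariabilityRanker,
    apply_eligibility,
    generate_roster,
    impact_config,
    plant_extreme,
    run_impact,
    run_variability,
    variability_config,
)
from conftest import make_small_tables


def single_basin_tables():
    basins, subbasins = make_small_tables()
    basins = basins.iloc[[0]].reset_index(drop=True)
    subbasins = subbasins[subbasins["basin_id"] == "A"].reset_index(drop=True)
    return basins, subbasins


class TestImpact:
    def test_planted_maximum_takes_national_ordinal_1(self, default_roster):
        basins, subbasins, pid = plant_extreme(*default_roster, "R05", "impact_dominant")
        results = run_impact(basins, subbasins)
        row = results.loc[results["basin_id"] == pid].iloc[0]
        assert row["national_ordinal"] == 1
        assert row["region_ordinal"] == 1

    def test_identical_basins_tie_everywhere(self):
        basins, subbasins = make_small_tables()
        # clone basin A's values onto B and C
        for col in basins.columns[2:]:
            basins[col] = basins[col].iloc[0]
        a_vals = subbasins[subbasins["basin_id"] == "A"].iloc[:, 2:].to_numpy()
        for bid in ("B", "C"):
            subbasins.loc[subbasins["basin_id"] == bid, subbasins.columns[2:]] = a_vals
        results = run_impact(basins, subbasins)
        assert results["overall"].nunique() == 1

    def test_single_basin_roster_overall(self):
        """Singleton ranks are 1.0, receptor normalizes over 5 variables."""
        results = run_impact(*single_basin_tables())
        row = results.iloc[0]
        assert row["water_quality"] == pytest.approx(1.0)
        assert row["source"] == pytest.approx(1.0)
        assert row["receptor"] == pytest.approx(0.8)  # weight sum 4 over 5 vars
        assert row["overall"] == pytest.approx(2.8)

    def test_variable_ranks_use_full_roster(self, default_roster):
        """Dropping a region changes other basins' ranks (roster-wide scope)."""
        basins, subbasins = default_roster
        ranker = ImpactRanker().fit((basins, subbasins))
        keep = basins["region_id"] != "R01"
        basins2 = basins[keep].reset_index(drop=True)
        subbasins2 = subbasins[subbasins["basin_id"].isin(basins2["basin_id"])]
        ranker2 = ImpactRanker().fit((basins2, subbasins2.reset_index(drop=True)))
        common = ranker2.ranks_.index
        assert not ranker.ranks_.loc[common].equals(ranker2.ranks_)

    def test_deterministic_rerun(self, default_roster):
        r1 = run_impact(*default_roster)
        r2 = run_impact(*default_roster)
        pd.testing.assert_frame_equal(r1, r2)


class TestVariability:
    def test_planted_spread_takes_region_ordinal_1(self, default_roster):
        basins, subbasins, pid = plant_extreme(
            *default_roster, "R09", "variability_dominant"
        )
        results = run_variability(basins, subbasins, scope="region")
        row = results.loc[results["basin_id"] == pid].iloc[0]
        assert row["region_ordinal"] == 1
        assert not row["penalized"]

    def test_constant_subbasins_tie_all_range_variables(self):
        basins, subbasins = make_small_tables()
        for col in subbasins.columns[2:]:
            subbasins[col] = 1.0 if col != "tile_fraction" else 0.5
        ranker = VariabilityRanker(scope="national").fit((basins, subbasins))
        range_cols = [c for c in ranker.ranks_.columns if c.endswith("_range")]
        for col in range_cols:
            assert ranker.ranks_[col].nunique() == 1

    def test_penalized_basin_never_beats_unpenalized(self, default_roster):
        results = run_variability(*default_roster, scope="region")
        for _, grp in results.groupby("region_id"):
            if grp["penalized"].any() and (~grp["penalized"]).any():
                assert grp.loc[grp["penalized"], "overall"].max() < \
                    grp.loc[~grp["penalized"], "overall"].min()

    def test_top_basin_always_in_water_quality_top4(self, default_roster):
        """The eligibility gate guarantees the regional winner's WQ standing."""
        for seed in range(5):
            basins, subbasins = generate_roster(SyntheticConfig(seed=100 + seed))
            ranker = VariabilityRanker(scope="region").fit((basins, subbasins))
            res = ranker.results_
            raw_wq = ranker.category_scores_["water_quality"] + np.where(
                ranker.category_scores_["penalized"], ranker.config_.eligibility.penalty, 0
            )
            for region, grp in res.groupby("region_id"):
                winner = grp.loc[grp["region_ordinal"] == 1, "basin_id"].iloc[0]
                wq = raw_wq[grp["basin_id"]].sort_values(ascending=False)
                top4_floor = wq.iloc[min(3, len(wq) - 1)]
                assert raw_wq[winner] >= top4_floor

    def test_national_scope_applies_no_penalty(self, default_roster):
        results = run_variability(*default_roster, scope="national")
        assert not results["penalized"].any()
        for cat in ("water_quality", "factor", "receptor", "accuracy"):
            assert results[cat].between(0, 1).all()

    def test_scope_changes_ranks(self, default_roster):
        r_region = run_variability(*default_roster, scope="region")
        r_national = run_variability(*default_roster, scope="national")
        assert not r_region["overall"].equals(r_national["overall"])


class TestEligibility:
    def test_direct_penalty_arithmetic(self):
        scores = pd.DataFrame(
            {
                "region_id": ["r"] * 6,
                "water_quality": [0.9, 0.8, 0.7, 0.6, 0.5, 0.4],
            }
        )
        out = apply_eligibility(scores, top_k=4, penalty=5.0)
        assert list(out["water_quality"]) == pytest.approx(
            [0.9, 0.8, 0.7, 0.6, -4.5, -4.6]
        )
        assert list(out["penalized"]) == [False] * 4 + [True] * 2

    def test_small_region_unchanged(self):
        scores = pd.DataFrame(
            {"region_id": ["r"] * 3, "water_quality": [0.9, 0.5, 0.1]}
        )
        out = apply_eligibility(scores)
        assert not out["penalized"].any()
        assert list(out["water_quality"]) == [0.9, 0.5, 0.1]

    def test_tie_at_fourth_keeps_all_eligible(self):
        scores = pd.DataFrame(
            {"region_id": ["r"] * 5, "water_quality": [0.9, 0.8, 0.7, 0.6, 0.6]}
        )
        out = apply_eligibility(scores)
        assert not out["penalized"].any()


class TestStructuralInvariants:
    @pytest.mark.parametrize("approach", ["impact", "variability"])
    def test_region_ordinals_are_permutations(self, default_roster, approach):
        run = run_impact if approach == "impact" else run_variability
        results = run(*default_roster)
        for _, grp in results.groupby("region_id"):
            assert sorted(grp["region_ordinal"]) == list(range(1, len(grp) + 1))
        assert sorted(results["national_ordinal"]) == list(range(1, 164))

    @pytest.mark.parametrize("approach", ["impact", "variability"])
    def test_unpenalized_category_scores_unit_interval(self, default_roster, approach):
        run = run_impact if approach == "impact" else run_variability
        results = run(*default_roster)
        cats = (
            ("water_quality", "source", "receptor")
            if approach == "impact"
            else ("water_quality", "factor", "receptor", "accuracy")
        )
        ok = ~results["penalized"]
        for cat in cats:
            assert results.loc[ok, cat].between(0, 1).all()

    def test_permuting_basin_order_leaves_scores_unchanged(self, small_tables):
        basins, subbasins = small_tables
        shuffled = basins.sample(frac=1, random_state=3).reset_index(drop=True)
        r1 = run_impact(basins, subbasins).set_index("basin_id").sort_index()
        r2 = run_impact(shuffled, subbasins).set_index("basin_id").sort_index()
        pd.testing.assert_frame_equal(r1, r2)

    def test_monotonicity_in_one_ascending_variable(self, small_tables):
        """Raising one basin's receptor value never lowers its scores."""
        basins, subbasins = small_tables
        before = run_impact(basins, subbasins).set_index("basin_id")
        raised = basins.copy()
        raised.loc[raised["basin_id"] == "A", "pop_served_per_km2"] = 500.0
        after = run_impact(raised, subbasins).set_index("basin_id")
        assert after.loc["A", "receptor"] >= before.loc["A", "receptor"]
        assert after.loc["A", "overall"] >= before.loc["A", "overall"]
        assert after.loc["A", "national_ordinal"] <= before.loc["A", "national_ordinal"]

    def test_equal_weights_reduce_to_mean_of_ranks(self, small_tables):
        """With unit weights, the pipeline is a plain mean-of-ranks index."""
        basins, subbasins = small_tables
        cfg = impact_config()
        flat_vars = tuple(
            v.__class__(**{**v.__dict__, "weight": 1.0}) for v in cfg.variables
        )
        cfg = cfg.with_(variables=flat_vars)
        ranker = ImpactRanker(config=cfg).fit((basins, subbasins))
        res = ranker.results_.set_index("basin_id")
        # independent simple composite: mean rank per category, summed
        ranks = ranker.ranks_
        expected = sum(
            ranks[[v.name for v in cfg.variables_in(cat)]].mean(axis=1)
            for cat in cfg.categories
        )
        assert np.allclose(res["overall"], expected.reindex(res.index))
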