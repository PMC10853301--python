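# basinrank

Prioritize HUC04-sized river basins for nutrient (nitrogen and phosphorus)
water-quality studies.

National monitoring and research programs can study only a few dozen basins
in detail. `basinrank` implements two complementary multi-criteria ranking
approaches over basin/subbasin variable tables for choosing them:

- the **impact approach** asks *where are nutrient problems most urgent?* —
  it favors basins with high nutrient sources, high stream and groundwater
  concentrations, and exposed receptors (drinking-water populations, lakes
  and reservoirs, stream ecosystems, downstream receiving waters);
- the **variability approach** asks *where can a nutrient-process study learn
  the most?* — it favors basins whose HUC08 subbasins span wide ranges in
  concentrations and driving factors, include low-concentration subbasins
  (where biological response is strongest), and where current water-quality
  models predict poorly.

The ranked units are 163 HUC04-sized candidate basins grouped into 18
hydrologic regions covering the contiguous U.S.; each basin contains several
HUC08 subbasins whose modeled values (stream volumetrically weighted-mean
N and P concentrations, source yields, tile-drain fraction, runoff,
groundwater nitrate, load residuals) are the inputs.

## The scoring model

For each variable *v* and basin *b*, the unit-interval rank within a scope
(the full roster, or one hydrologic region) is the spreadsheet percent rank

```
rank_v(b) = #{b' : x_v(b') < x_v(b)} / (n - 1)
```

(ties share a rank; descending variables negate first; a singleton scope
ranks 1). Category scores are weighted rank sums divided by a normalizer;
for the impact approach the normalizer is the variable count, e.g.

```
WQ = (1.5·rank_shallow_gw_NO3 + 0.5·rank_public_supply_NO3
      + 1.0·rank_stream_N + 1.0·rank_stream_P) / 4
Overall_impact = 1.0·WQ + 1.0·Source + 1.0·Receptor
```

For the variability approach the normalizer is the category weight sum (so
every category spans [0, 1]) and

```
Overall_variability = 1.0·WQ + 1.0·Factor + 0.5·Receptor + 0.5·Accuracy
```

with subbasin "ranges" computed as interquartile ranges (p75 − p25, inclusive
linear interpolation), stream concentrations log10-transformed, minimum
concentrations ranked descending, and model accuracy the mean absolute
log-space load residual. At regional scope a basin outside its region's
top-4 water-quality scores has 5 points subtracted from that score, which
removes it from contention (the maximum attainable overall is 3.0). Exact
ties in overall scores break lexicographically by basin id, so output is
reproducible.

The pipelines are sklearn-style estimators (`ImpactRanker`,
`VariabilityRanker`, plus a reusable `PercentRanker` transformer); the
functions `run_impact` / `run_variability` are thin wrappers. A seeded
synthetic-roster generator (`SyntheticConfig`, `generate_roster`,
`plant_extreme`) emulates the 163-basin / 18-region roster so the whole
pipeline is testable without the study's geospatial data release.

## Worked example

```python
import basinrank as br

basins, subbasins = br.generate_roster(br.SyntheticConfig(seed=1))
impact = br.run_impact(basins, subbasins)
variability = br.run_variability(basins, subbasins, scope="region")

cols = ["basin_id", "region_id", "water_quality", "source", "receptor",
        "overall", "region_ordinal", "national_ordinal"]
print(impact.sort_values("national_ordinal").head(5)[cols].round(3).to_string(index=False))
print("top pick differs in", br.compare_top_picks(impact, variability), "of 18 regions")
print(len(br.select_top_n(variability, 2)), "priority basins")
```

prints

```
basin_id region_id  water_quality  source  receptor  overall  region_ordinal  national_ordinal
  R13B07       R13          0.798   0.700     0.512    2.010               1                 1
  R06B09       R06          0.848   0.636     0.473    1.957               1                 2
  R06B07       R06          0.797   0.575     0.571    1.943               2                 3
  R18B03       R18          0.683   0.669     0.589    1.941               1                 4
  R15B02       R15          0.633   0.727     0.577    1.936               1                 5
top pick differs in 16 of 18 regions
36 priority basins
```

Basin `R13B07` ranks first nationally under the impact approach: its
category scores say it sits near the top of the roster on water quality
(0.798) and sources (0.700) simultaneously. The two approaches pick a
different regional winner in 16 of the 18 synthetic regions — they measure
genuinely different things — and keeping each region's top 2 reduces the
163 candidates to 36 priority basins.

The same operations are available from a shell:

```sh
basinrank simulate --seed 1 --out roster/
basinrank impact --basins roster/basins.csv --subbasins roster/subbasins.csv --out impact.csv
basinrank variability --basins roster/basins.csv --subbasins roster/subbasins.csv \
    --scope region --out variability.csv
basinrank compare impact.csv variability.csv --out diff.csv
basinrank summarize impact.csv --out summary.csv
```

## Input formats

Two CSV tables (see `basinrank.io` for the full schemas): `basins.csv` with
one row per candidate basin (id, region, area, receptor variables) and
`subbasins.csv` with one row per HUC08 (parent basin id, concentrations,
source yields, tile fraction, runoff, groundwater nitrate, residuals).
Spreadsheet workbooks can be converted with
`basinrank.import_workbook_sheet`, mapping column names through a
user-supplied alias table. Variable lists, weights, directions and the
eligibility rule live in YAML configs (`basinrank/configs/`), so either
approach can be re-weighted without code changes.
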