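# Methods

## Problem and model

`basinrank` ranks HUC04-sized candidate basins (grouped into hydrologic
regions, HRs) for two distinct purposes: urgency of nutrient impact, and
suitability for nutrient-process studies. Both approaches share one
arithmetic core — percent-rank normalization of basin-level variables,
weighted category scores, and a weighted overall score — and differ in
their variable sets, ranking scopes, and an eligibility rule.

### Percent rank

For values x₁..xₙ in a scope, `rank(xᵢ) = #{j : xⱼ < xᵢ} / (n − 1)`, the
spreadsheet percent-rank convention. Properties that matter downstream:

- ties share the count-strictly-less rank; a tied maximum therefore ranks
  below 1 (only a unique maximum attains exactly 1), while the minimum of a
  non-constant scope always ranks 0;
- a singleton scope ranks 1.0 (a lone basin is trivially the regional top;
  the published roster never has single-basin regions, but the code allows
  them);
- NaN values neither receive nor influence ranks (see *Missing data*).

The `PercentRanker` transformer generalizes this to ranking new values
against a fitted reference; values beyond the reference saturate at 0 or 1.

### Aggregating HUC08 subbasins

Subbasin-carried variables are collapsed per basin with the inclusive
linear-interpolation percentile (position h = 1 + p(n − 1); p = 0 and 1 hit
the exact minimum and maximum — the spreadsheet convention, implemented via
`numpy.quantile(..., method="linear")`):

- `median` — impact-approach concentrations, sources, and groundwater
  nitrate. Gridded groundwater predictions are out of scope at the table
  level, so the basin value is the median over HUC08 values; a
  pre-aggregated basin column can be substituted by editing the config.
- `iqr_range` — p75 − p25, the variability approach's "range" (outlier
  damping). A single-subbasin basin degenerates to range 0 with a logged
  warning, not an error.
- `minimum` — minimum stream concentrations, ranked *descending* because
  biological response is strongest at low concentrations.
- `mean_abs` — model accuracy as the mean absolute signed log-space load
  residual. The sign of a residual says whether the model over- or
  under-predicts; its magnitude measures (un)predictability, which is what
  the study-suitability ranking needs, so magnitudes are averaged.

Stream concentrations are log10-transformed before ranging/minimum-taking.
Zeros are floored at log10 of half the basin's smallest positive value
(computed as a difference of logs to avoid underflow); an all-zero multiset
passes through as zeros with a warning. The floor is per basin, since the
transform is applied to each basin's multiset before aggregation.

### Categories and overall scores

- Impact (14 variables): water quality (shallow groundwater nitrate weight
  1.5, public-supply-depth nitrate 0.5, stream N and P medians 1.0),
  sources (five unit-weight N/P source yields), receptors (population
  served, percent waterbodies, biotic index at 1.0; delivered N and P
  yields at 0.5). Category score = weighted rank sum / variable count, so
  the receptor category spans [0, 0.8] (weight sum 4 over 5 variables) —
  matching the printed "/4" water-quality normalization while the text
  describes dividing by the number of variables. Overall = WQ + Source +
  Receptor, every variable ranked across the full roster even for regional
  reporting (small regional samples would otherwise inflate rank gaps).
- Variability (20 variables): water quality (log-concentration IQRs and
  descending minima, 0.5 each), factors (nine IQRs, weights 0.5 or 1.0),
  accuracy (two mean-absolute residuals at 1.0), receptors (same five as
  impact). Category score = weighted rank sum / category weight sum, which
  reconciles "ranks were summed" with category scores displayed on a 0–1
  scale. Overall = 1.0·WQ + 1.0·Factor + 0.5·Receptor + 0.5·Accuracy;
  ranks are computed within each HR (`scope="region"`) or roster-wide
  (`scope="national"`).

Both normalizers are config-switchable (`category_normalization`), as is
re-weighting any variable, because the "/5 vs /4" receptor choice and the
category-rank reading of the overall equation are genuinely open; the
defaults above are the package's reading.

### Eligibility penalty

At regional scope, a basin whose water-quality category score is strictly
below the 4th-highest in its HR gets 5.0 subtracted from that score and is
flagged `penalized`. Ties with the 4th score stay eligible; regions with
≤ 4 basins are untouched. Since the maximum attainable overall is 3.0, a
penalized basin can never outrank an unpenalized one — the gate guarantees
every region's winner offers a wide, low-reaching concentration gradient.
National-scope scoring applies no penalty by default (the penalty is
defined per-HR); both behaviors are exposed through the config.

### Ordinals and ties

Final ordinals (1 = highest priority) are assigned within each region and
nationally on descending overall score, breaking exact ties
lexicographically by basin id. The tie-break is arbitrary but deterministic:
identical inputs always produce byte-identical output files.

## Missing data

A basin with no value for a variable keeps its other scores: the variable
is dropped from that basin's category score and the normalizer shrinks by
one count (variable-count convention) or by the variable's weight
(weight-sum convention), with a warning logged per drop. The alternative —
scoring gaps as rank 0 — would silently rank data gaps as "least impacted".
`missing_policy="strict"` turns any gap into an error instead.

## Synthetic rosters

The generator emulates the published roster's shape: 18 regions, 163 basins
(one region of 10, seventeen of 9 by default), 4–12 subbasins per basin.
Distributions are chosen for generic realism of this data type, not
calibrated to the data release:

- source yields and concentrations log-normal (within-region σ = 0.7 on the
  log scale) with Normal regional location shifts (σ = 0.5) — positive skew
  with heavy right tails, exercising the log transform and rank ties;
  national medians are order-of-magnitude realistic (e.g. 3000 kg/km²/yr
  fertilizer+manure N, 1.5 mg/L stream N, 0.08 mg/L stream P);
- tile-drain fraction Beta (regionally rescaled), runoff Gamma
  (mean 0.35 m/yr), biotic index Beta(2, 2) shifted with basin agricultural
  intensity, load residuals Normal with σ = 30 % (log-space percent error);
- stream concentrations are a monotone function of local source yield plus
  noise: z_conc = ρ·z_source + √(1 − ρ²)·ε with coupling ρ = 0.6 by
  default, so the source-score/water-quality-score association seen in real
  basins is reproducible and tunable;
- a single seed spawns one substream per region (`numpy` SeedSequence), so
  rosters are bit-stable and partially regenerable.

What the generator does *not* emulate: spatial autocorrelation between
neighboring basins, network routing (delivered yields are a noisy fraction
of local sources), real column marginals, and region-specific covariance
structure. Passing tests therefore demonstrate correctness of the ranking
arithmetic and its guarantees, not agreement with the study's published
basin identities — reproducing those requires the study's released variable
tables, which are external to this package. The published per-region top-2
selections themselves ship as a small reference CSV for comparison-level
checks (the 15-of-18 top-pick disagreement).

### Planted extremes

`plant_extreme` overwrites one basin to force a known outcome, providing a
construction-based oracle for the pipelines:

- `impact_dominant`: all 14 impact variables set to 1.05× the roster
  maximum (bounded variables capped at their bound) — must take national
  ordinal 1 under the impact approach;
- `variability_dominant`: subbasins alternate between a low extreme (half
  the roster-minimum positive concentration; bound floors elsewhere) and
  1.05× the roster maximum, residuals alternate ±1.05× the largest
  magnitude, receptors set to the roster top — must take region ordinal 1
  under the regional variability approach, and its region-best
  water-quality score keeps it eligible. Requires ≥ 4 subbasins (with
  fewer, quartile interpolation crosses the low/high gap and the dominance
  argument breaks); the generator's default minimum is 4.

When both plant modes are requested, the impact plant is applied last so
its roster-maximum guarantee survives the inflated values the variability
plant introduces. At most one impact-dominant plant is allowed per roster
(two basins cannot both be national #1) and one plant per region.

## Numerical and scale choices

- All scoring is exact rational arithmetic on ranks up to float rounding;
  no iteration, no randomness — determinism is asserted at the byte level.
- Tests and the acceptance script run full 163-basin rosters (≈ 1250
  subbasins); a complete pipeline run takes well under a second, the whole
  suite well under the minutes range, and the planted-recovery check uses
  20 independent seeded rosters as its sample.
- CSV is the interchange format; floats are written at full precision
  (`repr` round-trip), so load → write → load is value-identical.

## Known limitations

- Ranking quality inherits everything the input models get wrong; the
  accuracy category only *uses* residuals, it does not propagate their
  uncertainty into rank uncertainty.
- Percent ranks discard distances: a basin marginally below another loses
  exactly as much as one far below. The IQR/minimum variables mitigate but
  do not remove scale dependence — variability rankings depend on the HUC08
  subbasin scale at which spread is measured.
- The two approaches are deliberately not blended into one score; they
  answer different questions and are meant to be used sequentially.
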