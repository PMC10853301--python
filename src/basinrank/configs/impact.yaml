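# Impact approach: where are nutrient problems most urgent?
# 14 variables in three categories. Variable ranks are percent ranks across
# the full roster; category scores are weighted rank sums divided by the
# number of variables in the category; overall = WQ + Source + Receptor.
approach: impact
category_normalization: by_variable_count
category_weights:
  water_quality: 1.0
  source: 1.0
  receptor: 1.0
eligibility:
  enabled: false
variables:
  # --- water quality (4): nutrient concentrations in groundwater and streams
  - name: gw_shallow_no3_median
    category: water_quality
    source_column: gw_shallow_no3
    level: subbasin
    aggregation: median
    weight: 1.5
  - name: gw_ps_no3_median
    category: water_quality
    source_column: gw_ps_no3
    level: subbasin
    aggregation: median
    weight: 0.5
  - name: stream_N_median
    category: water_quality
    source_column: stream_N_vwm
    level: subbasin
    aggregation: median
    weight: 1.0
  - name: stream_P_median
    category: water_quality
    source_column: stream_P_vwm
    level: subbasin
    aggregation: median
    weight: 1.0
  # --- sources (5): anthropogenic N and P inputs, kg/km2/yr
  - name: fertmanure_N_median
    category: source
    source_column: fertmanure_N
    level: subbasin
    aggregation: median
    weight: 1.0
  - name: fertmanure_P_median
    category: source
    source_column: fertmanure_P
    level: subbasin
    aggregation: median
    weight: 1.0
  - name: wwtp_N_median
    category: source
    source_column: wwtp_N
    level: subbasin
    aggregation: median
    weight: 1.0
  - name: wwtp_P_median
    category: source
    source_column: wwtp_P
    level: subbasin
    aggregation: median
    weight: 1.0
  - name: septic_N_median
    category: source
    source_column: septic_N
    level: subbasin
    aggregation: median
    weight: 1.0
  # --- receptors (5): exposure of people and ecosystems
  - name: pop_served
    category: receptor
    source_column: pop_served_per_km2
    level: basin
    aggregation: none
    weight: 1.0
  - name: pct_waterbodies
    category: receptor
    source_column: pct_waterbodies
    level: basin
    aggregation: none
    weight: 1.0
  - name: biotic_index
    category: receptor
    source_column: biotic_index
    level: basin
    aggregation: none
    weight: 1.0
  - name: delivered_N_yield
    category: receptor
    source_column: delivered_N_yield
    level: basin
    aggregation: none
    weight: 0.5
  - name: delivered_P_yield
    category: receptor
    source_column: delivered_P_yield
    level: basin
    aggregation: none
    weight: 0.5
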