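# Variability approach: where can a nutrient-process study learn the most?
# 20 variables in four categories. Ranges are interquartile (p75 - p25) over
# a basin's HUC08 subbasins; stream concentrations are log10-transformed
# before ranging; minimum concentrations rank descending (low minima are
# favorable because biological response is strongest at low concentrations).
# Category scores are weighted rank sums divided by the category weight sum
# (each category on 0-1); overall = 1.0*WQ + 1.0*Factor + 0.5*Receptor
# + 0.5*Accuracy, after the top-4 water-quality eligibility penalty.
approach: variability
category_normalization: by_weight_sum
category_weights:
  water_quality: 1.0
  factor: 1.0
  receptor: 0.5
  accuracy: 0.5
eligibility:
  enabled: true
  top_k: 4
  penalty: 5.0
  scope: region
variables:
  # --- water quality (4): spread and floor of stream nutrient concentrations
  - name: stream_N_log_range
    category: water_quality
    source_column: stream_N_vwm
    level: subbasin
    aggregation: iqr_range
    transform: log10_floored
    weight: 0.5
  - name: stream_P_log_range
    category: water_quality
    source_column: stream_P_vwm
    level: subbasin
    aggregation: iqr_range
    transform: log10_floored
    weight: 0.5
  - name: stream_N_log_min
    category: water_quality
    source_column: stream_N_vwm
    level: subbasin
    aggregation: minimum
    transform: log10_floored
    direction: descending
    weight: 0.5
  - name: stream_P_log_min
    category: water_quality
    source_column: stream_P_vwm
    level: subbasin
    aggregation: minimum
    transform: log10_floored
    direction: descending
    weight: 0.5
  # --- factors (9): spread of drivers of stream nutrient concentrations
  - name: fertmanure_N_range
    category: factor
    source_column: fertmanure_N
    level: subbasin
    aggregation: iqr_range
    weight: 0.5
  - name: fertmanure_P_range
    category: factor
    source_column: fertmanure_P
    level: subbasin
    aggregation: iqr_range
    weight: 0.5
  - name: wwtp_N_range
    category: factor
    source_column: wwtp_N
    level: subbasin
    aggregation: iqr_range
    weight: 0.5
  - name: wwtp_P_range
    category: factor
    source_column: wwtp_P
    level: subbasin
    aggregation: iqr_range
    weight: 0.5
  - name: septic_N_range
    category: factor
    source_column: septic_N
    level: subbasin
    aggregation: iqr_range
    weight: 1.0
  - name: tile_fraction_range
    category: factor
    source_column: tile_fraction
    level: subbasin
    aggregation: iqr_range
    weight: 1.0
  - name: runoff_range
    category: factor
    source_column: runoff
    level: subbasin
    aggregation: iqr_range
    weight: 1.0
  - name: gw_shallow_no3_range
    category: factor
    source_column: gw_shallow_no3
    level: subbasin
    aggregation: iqr_range
    weight: 0.5
  - name: gw_ps_no3_range
    category: factor
    source_column: gw_ps_no3
    level: subbasin
    aggregation: iqr_range
    weight: 0.5
  # --- model accuracy (2): magnitude of load-prediction residuals
  - name: resid_N_mean_abs
    category: accuracy
    source_column: resid_N
    level: subbasin
    aggregation: mean_abs
    weight: 1.0
  - name: resid_P_mean_abs
    category: accuracy
    source_column: resid_P
    level: subbasin
    aggregation: mean_abs
    weight: 1.0
  # --- receptors (5): exposure of people and ecosystems (same as impact)
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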