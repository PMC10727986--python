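{
  "version": 1,
  "scale_thresholds_um": {"micro_below": 100, "macro_above": 1000},
  "selected_features": [
    {"rank": 1,  "key": "n_vessels__epi_svp__2d",          "scale": "mesoscale",  "diabetes_change": "down", "p_value": "<0.001"},
    {"rank": 2,  "key": "n_junctions__epi_svp__2d",        "scale": "mesoscale",  "diabetes_change": "down", "p_value": "<0.001"},
    {"rank": 3,  "key": "n_j2j_branches__dermal__2d",      "scale": "mesoscale",  "diabetes_change": "down", "p_value": "0.011"},
    {"rank": 4,  "key": "n_j2j_branches__epi_svp__2d",     "scale": "mesoscale",  "diabetes_change": "down", "p_value": "0.001"},
    {"rank": 5,  "key": "layer_thickness__dermal__3d",     "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.174"},
    {"rank": 6,  "key": "total_vessel_area__dermal__3d",   "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.165"},
    {"rank": 7,  "key": "layer_area__dermal__2d",          "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.126"},
    {"rank": 8,  "key": "avg_vessel_length__dermal__2d",   "scale": "microscale", "diabetes_change": "down", "p_value": "0.031"},
    {"rank": 9,  "key": "n_j2e_branches__epi_svp__2d",     "scale": "mesoscale",  "diabetes_change": "down", "p_value": "<0.001"},
    {"rank": 10, "key": "n_j2e_branches__epi_svp__3d",     "scale": "mesoscale",  "diabetes_change": "up",   "p_value": "0.387"},
    {"rank": 11, "key": "n_vessels__epi_svp__3d",          "scale": "mesoscale",  "diabetes_change": "up",   "p_value": "0.690"},
    {"rank": 12, "key": "layer_thickness__epi_svp__3d",    "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.170"},
    {"rank": 13, "key": "n_vessels__dermal__3d",           "scale": "mesoscale",  "diabetes_change": "down", "p_value": "0.093"},
    {"rank": 14, "key": "total_vessel_area__epi_svp__3d",  "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.153"},
    {"rank": 15, "key": "layer_area__dermal__3d",          "scale": "macroscale", "diabetes_change": "down", "p_value": "0.546"},
    {"rank": 16, "key": "n_junctions__epi_svp__3d",        "scale": "mesoscale",  "diabetes_change": "up",   "p_value": "0.719"},
    {"rank": 17, "key": "avg_vessel_area__dermal__2d",     "scale": "microscale", "diabetes_change": "up",   "p_value": "0.904"},
    {"rank": 18, "key": "n_j2j_branches__epi_svp__3d",     "scale": "mesoscale",  "diabetes_change": "up",   "p_value": "0.737"},
    {"rank": 19, "key": "total_vessel_area__dermal__2d",   "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.993"},
    {"rank": 20, "key": "n_junctions__dermal__3d",         "scale": "mesoscale",  "diabetes_change": "down", "p_value": "0.084"},
    {"rank": 21, "key": "n_j2j_branches__dermal__3d",      "scale": "mesoscale",  "diabetes_change": "down", "p_value": "0.084"},
    {"rank": 22, "key": "total_vessel_area__epi_svp__2d",  "scale": "macroscale", "diabetes_change": "down", "p_value": "0.159"},
    {"rank": 23, "key": "layer_area__epi_svp__3d",         "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.972"},
    {"rank": 24, "key": "avg_vessel_volume__dermal__3d",   "scale": "microscale", "diabetes_change": "up",   "p_value": "0.010"},
    {"rank": 25, "key": "avg_vessel_area__epi_svp__2d",    "scale": "microscale", "diabetes_change": "up",   "p_value": "0.595"},
    {"rank": 26, "key": "layer_area__epi_svp__2d",         "scale": "macroscale", "diabetes_change": "down", "p_value": "0.181"},
    {"rank": 27, "key": "n_j2e_branches__dermal__3d",      "scale": "mesoscale",  "diabetes_change": "down", "p_value": "0.279"},
    {"rank": 28, "key": "layer_thickness__dermal__2d",     "scale": "macroscale", "diabetes_change": "up",   "p_value": "0.374"},
    {"rank": 29, "key": "layer_thickness__epi_svp__2d",    "scale": "macroscale", "diabetes_change": "down", "p_value": "0.161"},
    {"rank": 30, "key": "avg_vessel_volume__epi_svp__3d",  "scale": "microscale", "diabetes_change": "up",   "p_value": "0.138"},
    {"rank": 31, "key": "avg_vessel_diameter__dermal__3d", "scale": "microscale", "diabetes_change": "up",   "p_value": "0.035"},
    {"rank": 32, "key": "avg_vessel_diameter__epi_svp__3d","scale": "microscale", "diabetes_change": "up",   "p_value": "0.094"}
  ],
  "stage_trends": [
    {"key": "n_j2j_branches__dermal__2d",    "direction": "decrease"},
    {"key": "layer_thickness__dermal__3d",   "direction": "decrease"},
    {"key": "total_vessel_area__dermal__3d", "direction": "decrease"},
    {"key": "avg_vessel_length__dermal__2d", "direction": "decrease"},
    {"key": "n_vessels__dermal__3d",         "direction": "decrease"},
    {"key": "n_junctions__dermal__3d",       "direction": "decrease"},
    {"key": "n_j2j_branches__dermal__3d",    "direction": "decrease"},
    {"key": "n_vessels__epi_svp__2d",        "direction": "increase"},
    {"key": "n_junctions__epi_svp__2d",      "direction": "increase"},
    {"key": "n_j2j_branches__epi_svp__2d",   "direction": "increase"},
    {"key": "avg_vessel_area__epi_svp__2d",  "direction": "increase"}
  ]
}
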