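{
  "physiology": {
    "renal_cortex_volume_L": 0.216,
    "pt_fraction_of_cortex": 0.3,
    "pct_fraction_of_pt": 0.7,
    "bladder_volume_L": 0.2,
    "gfr_L_per_h": 6.5,
    "urine_outflow_L_per_h": 0.6,
    "flow_decrement": 0.074
  },
  "transporters": {
    "healthy": {"vmax1_mmol_per_h": 20.0, "vmax2_mmol_per_h": 93.5, "km1_mM": 0.5, "km2_mM": 4.0},
    "t2dm":    {"vmax1_mmol_per_h": 20.0, "vmax2_mmol_per_h": 110.0, "km1_mM": 0.5, "km2_mM": 4.0}
  },
  "drugs": {
    "dapagliflozin": {"molecular_weight": 409.0, "free_fraction": 0.07, "ki1_nM": 400.0, "ki2_nM": 0.3},
    "canagliflozin": {"molecular_weight": 454.0, "free_fraction": 0.01, "ki1_nM": 200.0, "ki2_nM": 0.6}
  },
  "clamp_arm_ranges": {
    "healthy_baseline": {"gfr_L_per_h": [5.66, 7.38], "urine_outflow_L_per_h": [0.63, 1.20]},
    "healthy_drug":     {"gfr_L_per_h": [5.19, 7.41], "urine_outflow_L_per_h": [0.78, 1.40]},
    "t2dm_baseline":    {"gfr_L_per_h": [6.52, 7.62], "urine_outflow_L_per_h": [0.54, 1.24]},
    "t2dm_drug":        {"gfr_L_per_h": [5.07, 7.53], "urine_outflow_L_per_h": [0.80, 1.20]}
  },
  "calibration_starting_points": {
    "vmax1": 14.0,
    "vmax2_t2dm": 126.0,
    "healthy_vmax2_prop": 1.0,
    "km1": 1.8,
    "km2": 4.9,
    "ki2": 6.0
  }
}
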