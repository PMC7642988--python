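{
  "schema": "cardiopop/expected-v1",
  "description": "Reference values for report comparison: published single-model APD changes of the human epicardial model and their comparison tolerances (relative, fraction).",
  "values": {
    "cq_apd_prolongation_pct": {"value": 43.0, "rtol": 0.15},
    "azm_apd_prolongation_pct": {"value": 29.0, "rtol": 0.15},
    "combined_apd_prolongation_ms": {"value": 177.0, "rtol": 0.15},
    "combined_rate_reduction_pct": {"value": 16.0, "rtol": 0.15},
    "control_iso_reduction_pct": {"value": 21.0, "rtol": 0.15}
  }
}
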