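{
  "schema": "cardiopop/experiment-v1",
  "seed": 0,
  "protocol": {"frequency_hz": 1.0, "n_prepace": 50, "n_record": 2, "min_prepace": 10, "steady_state_tol_ms": 0.05},
  "conditions": [
    {"drugs": [], "frequency_hz": 1.0}
  ]
}
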