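{
  "schema": "cardiopop/experiment-v1",
  "seed": 0,
  "protocol": {"frequency_hz": 1.0, "n_prepace": 1000, "n_record": 2},
  "conditions": [
    {"drugs": [], "frequency_hz": 1.0},
    {"drugs": [], "frequency_hz": 2.0},
    {"drugs": [], "frequency_hz": 2.0, "iso_fraction": 1.0},
    {"drugs": ["CQ"], "frequency_hz": 1.0},
    {"drugs": ["CQ"], "frequency_hz": 2.0},
    {"drugs": ["CQ"], "frequency_hz": 2.0, "iso_fraction": 1.0},
    {"drugs": ["AZM"], "frequency_hz": 1.0},
    {"drugs": ["AZM"], "frequency_hz": 2.0},
    {"drugs": ["AZM"], "frequency_hz": 2.0, "iso_fraction": 1.0},
    {"drugs": ["CQ", "AZM"], "frequency_hz": 1.0},
    {"drugs": ["CQ", "AZM"], "frequency_hz": 2.0},
    {"drugs": ["CQ", "AZM"], "frequency_hz": 2.0, "iso_fraction": 1.0}
  ]
}
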