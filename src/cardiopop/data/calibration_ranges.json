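{
  "schema": "cardiopop/calibration-v1",
  "description": "Physiological acceptance windows (mean +/- 3 SD of experimental human epicardial reference values) applied to each variant's drug-free 1 Hz baseline. The windows are wide relative to the sampled conductance variability, so an unperturbed Normal(1.0, 0.2) population is retained essentially in full.",
  "apd90_ms": [120.0, 450.0],
  "rmp_mV": [-98.0, -75.0]
}
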