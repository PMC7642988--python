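{
  "schema": "cardiopop/iso-effects-v1",
  "description": "Phenomenological maximal (1 uM) isoproterenol effect set for the epicardial model: PKA-mediated up-scaling of IKs and ICaL dominates, with hyperpolarizing shifts of the ICaL steady-state gates and a secondary Na+/K+-pump stimulation. The IKs factor is calibrated to the reported drug-free response (2 Hz + 1 uM ISO shortens APD90 by 21% vs 1 Hz); the ICaL and INaK factors follow the magnitudes reported for beta-adrenergic stimulation of ventricular myocytes.",
  "targets": {
    "IKs": {
      "g_mult": 9.14
    },
    "ICaL": {
      "g_mult": 2.2,
      "dv_act_shift_mV": -10.0,
      "dv_inact_shift_mV": -6.0
    },
    "INaK": {
      "g_mult": 1.3
    }
  }
}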