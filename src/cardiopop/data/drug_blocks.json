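{
  "schema": "cardiopop/drug-blocks-v1",
  "description": "Per-current Hill parameters for chloroquine and azithromycin multichannel block, with reference clinical concentrations (uM). IKr/IK1 dominance for CQ and IKr/Ito dominance for AZM follow patch-clamp screens in heterologous expression systems; IC50 values are calibrated so the default epicardial model reproduces the reported APD changes at the reference concentrations.",
  "drugs": {
    "CQ": {
      "concentration_uM": 5.0,
      "channels": {
        "IKr": {
          "ic50_uM": 6.1741,
          "hill": 1.0
        },
        "IK1": {
          "ic50_uM": 11.67,
          "hill": 1.0
        },
        "INa": {
          "ic50_uM": 45.0,
          "hill": 1.0
        },
        "INaL": {
          "ic50_uM": 45.0,
          "hill": 1.0
        },
        "ICaL": {
          "ic50_uM": 66.4,
          "hill": 1.0
        },
        "Ito": {
          "ic50_uM": 95.0,
          "hill": 1.0
        },
        "IKs": {
          "ic50_uM": 57.5,
          "hill": 1.0
        }
      }
    },
    "AZM": {
      "concentration_uM": 20.0,
      "channels": {
        "IKr": {
          "ic50_uM": 36.0203,
          "hill": 1.0
        },
        "Ito": {
          "ic50_uM": 91.1,
          "hill": 1.0
        },
        "INa": {
          "ic50_uM": 380.0,
          "hill": 1.0
        },
        "INaL": {
          "ic50_uM": 230.0,
          "hill": 1.0
        },
        "ICaL": {
          "ic50_uM": 380.0,
          "hill": 1.0
        },
        "IK1": {
          "ic50_uM": 980.0,
          "hill": 1.0
        },
        "IKs": {
          "ic50_uM": 380.0,
          "hill": 1.0
        }
      }
    }
  }
}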