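{
  "schema": "cardiopop/state-v1",
  "description": "Published resting initial conditions of the ORd 2011 human ventricular model (epicardial runs start here and are prepaced to steady state).",
  "state": {
    "v": -87.0,
    "nai": 7.0,
    "nass": 7.0,
    "ki": 145.0,
    "kss": 145.0,
    "cai": 1.0e-4,
    "cass": 1.0e-4,
    "cansr": 1.2,
    "cajsr": 1.2,
    "m": 0.0,
    "hf": 1.0,
    "hs": 1.0,
    "j": 1.0,
    "hsp": 1.0,
    "jp": 1.0,
    "mL": 0.0,
    "hL": 1.0,
    "hLp": 1.0,
    "a": 0.0,
    "iF": 1.0,
    "iS": 1.0,
    "ap": 0.0,
    "iFp": 1.0,
    "iSp": 1.0,
    "d": 0.0,
    "ff": 1.0,
    "fs": 1.0,
    "fcaf": 1.0,
    "fcas": 1.0,
    "jca": 1.0,
    "nca": 0.0,
    "ffp": 1.0,
    "fcafp": 1.0,
    "xrf": 0.0,
    "xrs": 0.0,
    "xs1": 0.0,
    "xs2": 0.0,
    "xk1": 1.0,
    "Jrelnp": 0.0,
    "Jrelp": 0.0,
    "CaMKt": 0.0
  }
}
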