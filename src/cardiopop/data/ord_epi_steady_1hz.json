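{
 "schema": "cardiopop/state-v1",
 "description": "Unperturbed ORd epicardial model after 1,000 beats of 1 Hz prepacing (stimulus -80 uA/uF, 1 ms), computed with the cardiopop adaptive Rush-Larsen integrator.",
 "state": {
  "v": -87.81668748531916,
  "nai": 7.5312875687142835,
  "nass": 7.531366664716182,
  "ki": 143.68256223285854,
  "kss": 143.68253454279204,
  "cai": 7.780501081474753e-05,
  "cass": 7.663550760717544e-05,
  "cansr": 2.0202379721568793,
  "cajsr": 1.9776483498708077,
  "m": 0.007482190258752331,
  "hf": 0.6916546222169994,
  "hs": 0.6916445747944374,
  "j": 0.691589825873551,
  "hsp": 0.44744222103333403,
  "jp": 0.6915513623755393,
  "mL": 0.00019500271110756015,
  "hL": 0.4979820340362926,
  "hLp": 0.2726029521308474,
  "a": 0.0010136743454817493,
  "iF": 0.9995395419615423,
  "iS": 0.9995313376561801,
  "ap": 0.0005164976295023005,
  "iFp": 0.9995395422840435,
  "iSp": 0.999537794669893,
  "d": 2.4455633179743247e-09,
  "ff": 0.9999999904066242,
  "fs": 0.920854607372861,
  "fcaf": 0.9999999904066613,
  "fcas": 0.9998826760435612,
  "jca": 0.9999835954149847,
  "nca": 0.0018538284562161114,
  "ffp": 0.9999999904049149,
  "fcafp": 0.9999999904050201,
  "xrf": 8.264035598128052e-06,
  "xrs": 0.4300936402771099,
  "xs1": 0.24688635252454305,
  "xs2": 0.00019686190488456585,
  "xk1": 0.9968079170465264,
  "Jrelnp": 4.789373779422593e-07,
  "Jrelp": 5.985971861399742e-07,
  "CaMKt": 0.014406420642008033
 }
}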