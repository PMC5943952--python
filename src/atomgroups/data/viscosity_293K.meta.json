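{
  "descriptor": "log_eta_293K",
  "valid_groups": {
    "value": 76,
    "n": 501
  },
  "r2": {
    "value": 0.9831,
    "n": 460
  },
  "avg_dev": {
    "value": 0.07,
    "n": 460
  },
  "std_dev": {
    "value": 0.1,
    "n": 460
  },
  "cv_k": {
    "value": 10,
    "n": 413
  },
  "q2": {
    "value": 0.975,
    "n": 413
  },
  "cv_avg_dev": {
    "value": 0.08,
    "n": 413
  },
  "cv_std_dev": {
    "value": 0.11,
    "n": 413
  }
}
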