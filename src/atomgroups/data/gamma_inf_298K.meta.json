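{
  "descriptor": "log_gamma_inf_298K",
  "valid_groups": {
    "value": 75,
    "n": 675
  },
  "r2": {
    "value": 0.9789,
    "n": 634
  },
  "avg_dev": {
    "value": 0.21,
    "n": 634
  },
  "std_dev": {
    "value": 0.27,
    "n": 634
  },
  "cv_k": {
    "value": 10,
    "n": 616
  },
  "q2": {
    "value": 0.9737,
    "n": 616
  },
  "cv_avg_dev": {
    "value": 0.23,
    "n": 616
  },
  "cv_std_dev": {
    "value": 0.31,
    "n": 616
  }
}
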