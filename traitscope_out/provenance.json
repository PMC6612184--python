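{
  "B": 100000,
  "alpha": 0.05,
  "cohort_sizes": {},
  "contrasts": [],
  "databases": {},
  "seed": 0,
  "thresholds": {
    "abundant": 0.1,
    "all": 0.001
  },
  "traitscope_version": "0.1.0",
  "tree": null
}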