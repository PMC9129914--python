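{
  "version": 1,
  "window_size": 101,
  "coverage_min": 50,
  "end_convention": "five_prime",
  "min_mapq": 10,
  "shadow_range": 80,
  "control_rule": "each",
  "cutoffs": {
    "mrna": {"metric": "z", "treated_min": 10.0, "control_max": 7.0, "coverage_min": 50},
    "trna": {"metric": "mad", "treated_min": 40.0, "control_max": 40.0, "coverage_min": 50},
    "snrna": {"metric": "mad", "treated_min": 12.0, "control_max": 8.0, "coverage_min": 50},
    "snorna": {"metric": "mad", "treated_min": 12.0, "control_max": 8.0, "coverage_min": 50}
  },
  "dms": {
    "min_coverage": 350,
    "allowed_bases": ["A", "C"],
    "n_draws": 70,
    "half_window": 12
  }
}
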