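{
  "description": "Published Weibull accelerated-failure-time laws for time to PONV onset, one per treatment arm (intercept = location on log-time, log_scale = log of the AFT scale). Time unit: days.",
  "time_unit": "days",
  "arms": {
    "ramosetron": {"family": "weibull", "intercept": -2.0997, "log_scale": 0.8475},
    "no_antiemetic": {"family": "weibull", "intercept": -2.7831, "log_scale": 0.7985}
  }
}
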