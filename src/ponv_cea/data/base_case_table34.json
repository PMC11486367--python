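{
  "description": "Published base-case cost components (USD, payer + societal rows), totals and QALYs per arm, used as calibration anchors for the decision model.",
  "currency": "USD",
  "arms": {
    "ramosetron": {
      "components": {
        "prophylaxis": 13.94,
        "rescue_medication": 1.69,
        "staff_time": 1.18,
        "hospitalization": 0.07,
        "outpatient_after_discharge": 0.00,
        "transportation": 0.00,
        "patient_time": 0.00,
        "productivity_loss": 0.01
      },
      "qaly": 0.0121,
      "total_payer": 16.88,
      "total_societal": 16.89
    },
    "no_antiemetic": {
      "components": {
        "prophylaxis": 0.00,
        "rescue_medication": 7.84,
        "staff_time": 5.57,
        "hospitalization": 3.92,
        "outpatient_after_discharge": 0.01,
        "transportation": 0.00,
        "patient_time": 0.02,
        "productivity_loss": 1.37
      },
      "qaly": 0.0114,
      "total_payer": 17.33,
      "total_societal": 18.72
    }
  }
}
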