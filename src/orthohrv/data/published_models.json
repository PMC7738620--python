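{
  "R1_deltaRR": {
    "response_name": "delta_rr_mean",
    "response_units": "ms",
    "intercept": 1249.37,
    "coefficients": {
      "vo2max": 12.32,
      "training_load": 0.36,
      "hr_max": -8.83,
      "rpe": -5.9,
      "perceived_fatigue": -28.41
    },
    "adj_r2": 0.322,
    "aic": 1805.0,
    "notes": "Best AIC-ranked model for the orthostatic mean-RR delta. The running-text restatement rounds the RPE coefficient to -5.8; the tabulated -5.90 is canonical."
  },
  "R1pp_deltaLnRMSSD": {
    "response_name": "delta_ln_rmssd",
    "response_units": "ln(ms)",
    "intercept": 1.647,
    "coefficients": {
      "vo2max": 0.042,
      "training_load": 0.002,
      "hr_max": -0.017,
      "rpe": -0.019,
      "perceived_fatigue": -0.1,
      "stress": 0.092
    },
    "adj_r2": 0.141,
    "aic": 229.9,
    "notes": "Best AIC-ranked model for the orthostatic LnRMSSD delta."
  },
  "coach_deltaRR": {
    "response_name": "delta_rr_mean",
    "response_units": "ms",
    "intercept": 689.62,
    "coefficients": {
      "wb": -14.36,
      "hr_max": -2.06,
      "training_load": 0.35
    },
    "adj_r2": 0.194,
    "aic": 2033.0,
    "notes": "Field-friendly model using the summed well-being score instead of VO2max; lower explanatory power, use with caution."
  }
}
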