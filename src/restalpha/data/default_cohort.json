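{
  "comment": "Shipped demo cohort parameters. IAF means/SDs follow the reported group means with SD = SE*sqrt(24); amplitudes are source RMS in microvolts chosen to reproduce the reported posterior>frontal gradient and the right-posterior group asymmetry; lag means follow the reported right intra-hemispheric time lags (+7.04 ms HSG, -11.21 ms LSG) with an anterior-to-posterior (negative) lag elsewhere.",
  "HSG": {
    "group_label": "HSG",
    "iaf_mean_hz": {"frontal_L": 10.25, "frontal_R": 10.38, "posterior_L": 10.39, "posterior_R": 10.09},
    "iaf_sd_hz": {"frontal_L": 0.59, "frontal_R": 0.59, "posterior_L": 0.83, "posterior_R": 0.83},
    "amp_mean_uv": {"frontal_L": 1.15, "frontal_R": 1.15, "posterior_L": 3.05, "posterior_R": 2.65},
    "amp_sd_uv": {"frontal_L": 0.25, "frontal_R": 0.25, "posterior_L": 0.35, "posterior_R": 0.35},
    "coupling_strength": {"L": 0.5, "R": 0.35},
    "lag_ms_mean": {"L": -11.0, "R": 7.04},
    "lag_ms_sd": {"L": 8.0, "R": 8.0},
    "noise_exponent": 1.0,
    "background_uv": 1.5,
    "sensor_noise_uv": 1.0
  },
  "LSG": {
    "group_label": "LSG",
    "iaf_mean_hz": {"frontal_L": 10.25, "frontal_R": 10.38, "posterior_L": 10.39, "posterior_R": 10.70},
    "iaf_sd_hz": {"frontal_L": 0.59, "frontal_R": 0.59, "posterior_L": 0.83, "posterior_R": 0.83},
    "amp_mean_uv": {"frontal_L": 1.27, "frontal_R": 1.13, "posterior_L": 3.0, "posterior_R": 3.05},
    "amp_sd_uv": {"frontal_L": 0.25, "frontal_R": 0.25, "posterior_L": 0.35, "posterior_R": 0.35},
    "coupling_strength": {"L": 0.5, "R": 0.6},
    "lag_ms_mean": {"L": -11.0, "R": -11.21},
    "lag_ms_sd": {"L": 8.0, "R": 8.0},
    "noise_exponent": 1.0,
    "background_uv": 1.5,
    "sensor_noise_uv": 1.0
  }
}
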