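{
  "master_seed": 1,
  "cohort": {
    "n_motoneurons": 6,
    "nerves": ["deep_radial", "median_arm"],
    "duration_s": 40.0,
    "mean_rate_hz": 10.0,
    "dead_time_s": 0.003,
    "detect_probability": 0.6,
    "amplitude_mean_uv": 250.0,
    "amplitude_sd_uv": 100.0,
    "noise_sd_uv": 100.0
  },
  "measure": {"artifact_window_ms": [0.0, 3.0], "search_window_ms": [1.0, 50.0]},
  "coherence": {"window_len": 16384, "alpha": 0.05, "band_hz": [8.0, 12.0]},
  "conditioning": {"nerve": "deep_radial", "mode": "short", "min_triggers": 10},
  "stats": {"n_boot": 2000, "n_perm": 2000, "q": 0.05},
  "model": {"enabled": true, "duration_s": 30.0, "rise_ms": [1.0, 4.0, 8.0]}
}
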