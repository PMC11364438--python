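{
  "_comment": "Preset cohort parameters. All effect sizes are invented for the synthetic generators; they encode only the qualitative ordering observed in the assay (injured / older-at-injury / mated-female cohorts climb slower, with more dispersed headings and more pausing), with magnitudes chosen so that sham vs D31Inj separates with power >= 0.9 at 15 flies x 9 trials. Speeds in mm/s, heading_sd in degrees, startle_latency_mean in s, hazard parameters are Gompertz (scale/day, shape/day).",
  "male_sham":             {"mean_speed": 14.0, "speed_shape": 4.0, "heading_sd": 15.0, "pause_prob": 0.02,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "male_D3Inj":            {"mean_speed": 12.0, "speed_shape": 4.0, "heading_sd": 20.0, "pause_prob": 0.04,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "male_D17Inj":           {"mean_speed": 10.0, "speed_shape": 4.0, "heading_sd": 28.0, "pause_prob": 0.08,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "male_D31Inj":           {"mean_speed":  7.0, "speed_shape": 4.0, "heading_sd": 40.0, "pause_prob": 0.15,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_mated_sham":     {"mean_speed": 13.0, "speed_shape": 4.0, "heading_sd": 18.0, "pause_prob": 0.03,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_mated_D3Inj":    {"mean_speed": 10.5, "speed_shape": 4.0, "heading_sd": 25.0, "pause_prob": 0.06,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_mated_D17Inj":   {"mean_speed":  8.5, "speed_shape": 4.0, "heading_sd": 33.0, "pause_prob": 0.10,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_mated_D31Inj":   {"mean_speed":  6.0, "speed_shape": 4.0, "heading_sd": 48.0, "pause_prob": 0.20,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_virgin_sham":    {"mean_speed": 13.0, "speed_shape": 4.0, "heading_sd": 18.0, "pause_prob": 0.03,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_virgin_D3Inj":   {"mean_speed": 12.5, "speed_shape": 4.0, "heading_sd": 19.0, "pause_prob": 0.035, "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_virgin_D17Inj":  {"mean_speed": 12.0, "speed_shape": 4.0, "heading_sd": 20.0, "pause_prob": 0.04,  "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15},
  "female_virgin_D31Inj":  {"mean_speed": 11.5, "speed_shape": 4.0, "heading_sd": 21.0, "pause_prob": 0.045, "startle_latency_mean": 0.3, "hazard_scale": 0.000172, "hazard_shape": 0.1, "n_flies_default": 15}
}
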