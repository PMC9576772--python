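{
  "tract": "FO",
  "area_mode": 0.98,
  "area_median": 2.32,
  "diameter_mode": 1.41,
  "diameter_median": 1.81,
  "ellipticity_min": 0.7,
  "ellipticity_max": 0.9,
  "tortuosity_mean": 0.130,
  "tortuosity_sd": 0.088,
  "axonal_density": 1.1e7,
  "axonal_density_sd": 3.0e6,
  "volume_fraction": 0.51,
  "volume_fraction_sd": 0.05,
  "interlayer_area_cv": 0.10,
  "interlayer_semiaxis_delta": 0.05
}
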