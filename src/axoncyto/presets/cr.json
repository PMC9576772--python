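{
  "tract": "CR",
  "area_mode": 0.5,
  "area_median": 1.35,
  "diameter_mode": 1.00,
  "diameter_median": 1.30,
  "ellipticity_min": 0.6,
  "ellipticity_max": 0.9,
  "tortuosity_mean": 0.091,
  "tortuosity_sd": 0.07,
  "axonal_density": 1.5e7,
  "axonal_density_sd": 5.0e6,
  "volume_fraction": 0.37,
  "volume_fraction_sd": 0.21,
  "interlayer_area_cv": 0.10,
  "interlayer_semiaxis_delta": 0.05
}
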