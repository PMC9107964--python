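{
  "schema_version": 1,
  "window": {"x_min": 0.0, "y_min": 0.0, "side_x": 246.03, "side_y": 246.03},
  "quadrants": ["dorsal", "ventral", "nasal", "temporal"],
  "regions_per_quadrant": 4,
  "density_by_region": {
    "dorsal":   [1800.0, 2700.0, 3900.0, 5100.0],
    "temporal": [2600.0, 3300.0, 4100.0, 4900.0],
    "nasal":    [2900.0, 3400.0, 4000.0, 4600.0],
    "ventral":  [3200.0, 3600.0, 4000.0, 4400.0]
  },
  "diameter_mean_by_region": [9.5, 9.35, 9.2, 9.05],
  "diameter_sd_by_region": [0.45, 0.42, 0.4, 0.38],
  "ellipticity": 1.15,
  "ellipticity_sd": 0.05,
  "z_jitter_sd": 2.5
}
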