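{
  "phantom": {
    "baseline_volume": 310.0,
    "pulsation_amplitude": 13.0,
    "pulse_frequency": 1.5,
    "noise_sd": 30.0,
    "scan_duration": 5.0,
    "reconstruction_interval": 150.0,
    "rotation_time": 300.0,
    "voxel_spacing": [0.3, 0.3, 0.6],
    "grid_shape": [80, 80, 48],
    "include_skull": true
  },
  "threshold": "suggest",
  "crop_box": [22, 58, 22, 58, 31, 64],
  "mask_scheme": "vitro",
  "ellipse": {"cx": 17.7, "cy": 12.0, "a": 2.5, "b": 2.5, "init_slice": 47, "slice_range": [31, 64]},
  "expected_period": {"fixed_hz": 1.5},
  "noise_floor": 3.0,
  "dose": {"kvp": 80, "mas": 150, "scan_time_s": 5, "ctdi_vol": 108.60, "scan_length_cm": 3.84},
  "seed": 0
}
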