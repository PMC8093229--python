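{
  "phantom": {
    "baseline_volume": 310.0,
    "pulsation_amplitude": 5.0,
    "pulse_frequency": 1.0,
    "vessel_gap": 1.0,
    "noise_sd": 30.0,
    "drift_model": "plateau_then_linear_decay",
    "drift_plateau_fraction": 0.4,
    "drift_end_factor": 0.85,
    "scan_duration": 5.0,
    "reconstruction_interval": 50.0,
    "rotation_time": 300.0,
    "voxel_spacing": [0.3, 0.3, 0.6],
    "grid_shape": [80, 80, 48],
    "include_skull": true
  },
  "threshold": "suggest",
  "crop_box": [22, 57, 22, 58, 31, 64],
  "mask_scheme": "vivo",
  "polygons": [
    {"plane": "XY", "vertices": [[6.5, 6.5], [16.8, 6.5], [16.8, 17.4], [6.5, 17.4]], "slab": [0, 95]}
  ],
  "expected_period": {"fixed_hz": 1.0},
  "analysis_window": [2.0, 5.0],
  "noise_floor": 3.0,
  "dose": {"kvp": 80, "mas": 150, "scan_time_s": 5, "ctdi_vol": 108.2, "dlp": 415},
  "seed": 0
}
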