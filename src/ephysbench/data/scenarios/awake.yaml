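name: awake
duration_s: 10.0
sampling_rate_hz: 20000.0
refractory_s: 0.002
probe:
  file: four_tetrodes
tissue:
  kind: single
  volume_mm3: 1.5
  density_per_mm3: 300000.0
  active_fraction: 0.10
  pyramidal_fraction: 0.8
  rate_model:
    kind: uniform_bounds
    min_rate_hz: 0.5
    max_rate_hz: 12.0
interneuron_rate_factor: 5.0
attenuation:
  reference_distance_um: 50.0
  reference_amplitude_uv: 50.0
  minimum_distance_um: 10.0
  noise_radius_um: 100.0
background_radius_um: 250.0
templates:
  n: 20
  pyramidal_mix: 0.8
lfp:
  condition: awake
  rms_uv: 100.0
artefacts:
  classes: [mechanical_shock]
  rate_per_s: 10.0
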