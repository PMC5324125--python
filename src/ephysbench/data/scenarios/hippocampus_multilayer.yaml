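# CA1-style layered volume: stratum oriens / pyramidale / radiatum slabs
# with per-layer densities and logistic rate laws centred on the layers'
# characteristic rates; recorded with a 32-site (8 x 4 shank) polytrode.
name: hippocampus_multilayer
duration_s: 10.0
sampling_rate_hz: 20000.0
refractory_s: 0.002
probe:
  preset: polytrode_8x4
  center_um: [500.0, 500.0, 150.0]
tissue:
  kind: layered
  footprint_um: [1000.0, 1000.0]
  layers:
    - name: stratum_oriens
      thickness_um: 120.0
      density_per_mm3: 11300.0
      active_fraction: 0.10
      rate_model: {kind: logistic, loc_hz: 0.6, scale_hz: 0.06, min_rate_hz: 0.01}
    - name: stratum_pyramidale
      thickness_um: 55.0
      density_per_mm3: 272400.0
      active_fraction: 0.10
      rate_model: {kind: logistic, loc_hz: 0.4, scale_hz: 0.04, min_rate_hz: 0.01}
    - name: stratum_radiatum
      thickness_um: 240.0
      density_per_mm3: 1900.0
      active_fraction: 0.10
      rate_model: {kind: logistic, loc_hz: 0.2, scale_hz: 0.02, min_rate_hz: 0.01}
  pyramidal_fraction: 0.8
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
  rate_per_s: 1.0
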