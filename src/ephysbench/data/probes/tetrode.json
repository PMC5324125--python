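{
 "name": "tetrode",
 "site_diameter_um": 13.0,
 "sites": [
  [
   8.8388,
   8.8388,
   8.8388
  ],
  [
   8.8388,
   -8.8388,
   -8.8388
  ],
  [
   -8.8388,
   8.8388,
   -8.8388
  ],
  [
   -8.8388,
   -8.8388,
   8.8388
  ]
 ]
}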