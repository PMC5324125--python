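{
 "name": "four_tetrodes",
 "site_diameter_um": 13.0,
 "sites": [
  [
   -291.1612,
   8.8388,
   8.8388
  ],
  [
   -291.1612,
   -8.8388,
   -8.8388
  ],
  [
   -308.8388,
   8.8388,
   -8.8388
  ],
  [
   -308.8388,
   -8.8388,
   8.8388
  ],
  [
   -91.1612,
   8.8388,
   8.8388
  ],
  [
   -91.1612,
   -8.8388,
   -8.8388
  ],
  [
   -108.8388,
   8.8388,
   -8.8388
  ],
  [
   -108.8388,
   -8.8388,
   8.8388
  ],
  [
   108.8388,
   8.8388,
   8.8388
  ],
  [
   108.8388,
   -8.8388,
   -8.8388
  ],
  [
   91.1612,
   8.8388,
   -8.8388
  ],
  [
   91.1612,
   -8.8388,
   8.8388
  ],
  [
   308.8388,
   8.8388,
   8.8388
  ],
  [
   308.8388,
   -8.8388,
   -8.8388
  ],
  [
   291.1612,
   8.8388,
   -8.8388
  ],
  [
   291.1612,
   -8.8388,
   8.8388
  ]
 ]
}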