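{
 "name": "polytrode_8x4",
 "site_diameter_um": 13.0,
 "sites": [
  [
   -300.0,
   -8.66,
   -70.0
  ],
  [
   -300.0,
   8.66,
   -50.0
  ],
  [
   -300.0,
   -8.66,
   -30.0
  ],
  [
   -300.0,
   8.66,
   -10.0
  ],
  [
   -300.0,
   -8.66,
   10.0
  ],
  [
   -300.0,
   8.66,
   30.0
  ],
  [
   -300.0,
   -8.66,
   50.0
  ],
  [
   -300.0,
   8.66,
   70.0
  ],
  [
   -100.0,
   -8.66,
   -70.0
  ],
  [
   -100.0,
   8.66,
   -50.0
  ],
  [
   -100.0,
   -8.66,
   -30.0
  ],
  [
   -100.0,
   8.66,
   -10.0
  ],
  [
   -100.0,
   -8.66,
   10.0
  ],
  [
   -100.0,
   8.66,
   30.0
  ],
  [
   -100.0,
   -8.66,
   50.0
  ],
  [
   -100.0,
   8.66,
   70.0
  ],
  [
   100.0,
   -8.66,
   -70.0
  ],
  [
   100.0,
   8.66,
   -50.0
  ],
  [
   100.0,
   -8.66,
   -30.0
  ],
  [
   100.0,
   8.66,
   -10.0
  ],
  [
   100.0,
   -8.66,
   10.0
  ],
  [
   100.0,
   8.66,
   30.0
  ],
  [
   100.0,
   -8.66,
   50.0
  ],
  [
   100.0,
   8.66,
   70.0
  ],
  [
   300.0,
   -8.66,
   -70.0
  ],
  [
   300.0,
   8.66,
   -50.0
  ],
  [
   300.0,
   -8.66,
   -30.0
  ],
  [
   300.0,
   8.66,
   -10.0
  ],
  [
   300.0,
   -8.66,
   10.0
  ],
  [
   300.0,
   8.66,
   30.0
  ],
  [
   300.0,
   -8.66,
   50.0
  ],
  [
   300.0,
   8.66,
   70.0
  ]
 ]
}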