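# The five selected VNIR wavebands (nm) and the number of reference-axis
# points inside each closed interval. They bracket the chlorophyll absorption
# around 670 nm and the O-H stretching overtone bands near 920 and 970 nm,
# plus the short-wavelength pigment edge. Counts sum to 375.
intervals:
  - {lower: 350.00, upper: 400.02,  points: 63}
  - {lower: 639.88, upper: 690.76,  points: 67}
  - {lower: 830.92, upper: 930.41,  points: 136}
  - {lower: 940.65, upper: 960.35,  points: 27}
  - {lower: 966.90, upper: 1026.31, points: 82}
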