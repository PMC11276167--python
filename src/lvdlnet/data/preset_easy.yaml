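# "easy" simulator preset: large fraction coefficients relative to noise.
# Classes are separable by either modality alone (a nearest-centroid rule on
# raw spectra exceeds 95% accuracy); used for smoke tests and demos.
name: easy
libs:
  baseline: 50.0
  sigma_mult: 0.01
  sigma_add: 4.0
  gamma: 0.05
  base_amp:  [300, 500, 450, 150, 120, 200, 260, 1200, 900, 350, 800, 500, 180, 220, 260, 1000, 700, 320]
  frac_coef: [80, -120, -100, 40, 30, 60, 70, 400, 300, 90, -200, -130, 0, 50, 60, -250, -180, 70]
vnir:
  sigma_add: 0.0001
  baseline_knots: [[350, 0.30], [430, 0.45], [520, 0.58], [600, 0.62], [670, 0.64],
                   [760, 0.70], [850, 0.74], [950, 0.70], [1030, 0.66], [1100, 0.63]]
  bands:
    - {center: 670.0, width: 14.0, depth0: 0.15, depth_slope: 0.25}
    - {center: 920.0, width: 22.0, depth0: 0.08, depth_slope: 0.15}
    - {center: 970.0, width: 12.0, depth0: 0.10, depth_slope: -0.12}
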