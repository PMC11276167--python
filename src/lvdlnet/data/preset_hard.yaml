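# "hard" simulator preset: fraction coefficients a few noise standard
# deviations per 20% adulteration step. Interval features retain an advantage
# over peak-maximum features because noise can be averaged across the line
# profile while the peak maximum is biased by the noise extreme.
name: hard
libs:
  baseline: 50.0
  sigma_mult: 0.02
  sigma_add: 20.0
  gamma: 0.05
  base_amp:  [300, 500, 450, 150, 120, 200, 260, 1200, 900, 350, 800, 500, 180, 220, 260, 1000, 700, 320]
  frac_coef: [30, -40, -35, 12, 10, 20, 25, 90, 70, 30, -60, -40, 0, 15, 20, -70, -50, 20]
vnir:
  sigma_add: 0.001
  baseline_knots: [[350, 0.30], [430, 0.45], [520, 0.58], [600, 0.62], [670, 0.64],
                   [760, 0.70], [850, 0.74], [950, 0.70], [1030, 0.66], [1100, 0.63]]
  bands:
    - {center: 670.0, width: 14.0, depth0: 0.15, depth_slope: 0.04}
    - {center: 920.0, width: 22.0, depth0: 0.08, depth_slope: 0.025}
    - {center: 970.0, width: 12.0, depth0: 0.10, depth_slope: -0.03}
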