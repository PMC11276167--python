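# "complementary" simulator preset: the class signal is split between the two
# modalities and each modality's signal-to-noise ratio is set so that a
# single-modality classifier is capped well below perfect accuracy (adjacent
# adulteration levels overlap under the per-point noise). Because the two
# modalities carry independent noise, fusing them raises the effective SNR by
# about sqrt(2) and the fused model separates levels the single-modality
# models confuse. This is the preset that demonstrates fusion dominance.
name: complementary
libs:
  baseline: 50.0
  sigma_mult: 0.01
  sigma_add: 18.0
  gamma: 0.05
  base_amp:  [300, 500, 450, 150, 120, 200, 260, 1200, 900, 350, 800, 500, 180, 220, 260, 1000, 700, 320]
  frac_coef: [0, 0, 0, 0, 0, 0, 0, 100, 80, 0, 0, 0, 0, 0, 0, -85, 0, 0]
vnir:
  sigma_add: 0.0008
  baseline_knots: [[350, 0.30], [430, 0.45], [520, 0.58], [600, 0.62], [670, 0.64],
                   [760, 0.70], [850, 0.74], [950, 0.70], [1030, 0.66], [1100, 0.63]]
  bands:
    - {center: 670.0, width: 14.0, depth0: 0.15, depth_slope: 0.05}
    - {center: 920.0, width: 22.0, depth0: 0.08, depth_slope: 0.032}
    - {center: 970.0, width: 12.0, depth0: 0.10, depth_slope: -0.04}
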