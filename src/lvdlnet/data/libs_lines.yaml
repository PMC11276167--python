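# Registry of the 18 elemental emission-line intervals used for LIBS feature
# extraction. Columns: element symbol, line center (nm), interval bounds (nm),
# number of reference-axis points inside the closed interval, and the
# standardization operator that maps the interval to exactly 14 points.
#
# NOTE: the second Na D line is listed here as 589.52-589.71 nm. A 589.52-598.71
# window would be 9.19 nm wide, contradict the 14-point count, and overlap
# unrelated spectral regions; the upper bound is taken as 589.71 (digit slip).
target_points: 14
lines:
  - {element: C,  center: 247.86, lower: 247.72, upper: 248.04, points: 11, operation: zero_padding}
  - {element: Mg, center: 280.28, lower: 280.16, upper: 280.46, points: 11, operation: zero_padding}
  - {element: Mg, center: 285.23, lower: 285.08, upper: 285.37, points: 11, operation: zero_padding}
  - {element: Si, center: 288.17, lower: 288.09, upper: 288.26, points: 7,  operation: zero_padding}
  - {element: Al, center: 309.29, lower: 309.23, upper: 309.36, points: 10, operation: zero_padding}
  - {element: Ca, center: 315.89, lower: 315.79, upper: 315.98, points: 14, operation: retention}
  - {element: Ca, center: 317.93, lower: 317.83, upper: 318.08, points: 18, operation: interception}
  - {element: Ca, center: 393.34, lower: 393.12, upper: 393.51, points: 17, operation: interception}
  - {element: Ca, center: 396.79, lower: 396.65, upper: 396.94, points: 22, operation: interception}
  - {element: Ca, center: 422.64, lower: 422.49, upper: 422.75, points: 11, operation: zero_padding}
  - {element: Na, center: 588.99, lower: 588.90, upper: 589.11, points: 14, operation: retention}
  - {element: Na, center: 589.59, lower: 589.52, upper: 589.71, points: 14, operation: retention}
  - {element: N,  center: 742.53, lower: 742.30, upper: 742.75, points: 9,  operation: zero_padding}
  - {element: N,  center: 744.35, lower: 744.07, upper: 744.79, points: 14, operation: retention}
  - {element: N,  center: 746.89, lower: 746.66, upper: 747.38, points: 14, operation: retention}
  - {element: K,  center: 766.55, lower: 766.23, upper: 766.92, points: 14, operation: retention}
  - {element: K,  center: 769.89, lower: 769.62, upper: 770.31, points: 14, operation: retention}
  - {element: O,  center: 844.64, lower: 844.38, upper: 844.96, points: 14, operation: retention}
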