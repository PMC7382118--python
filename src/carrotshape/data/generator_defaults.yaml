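# Default morphometry ranges for the synthetic silhouette generator.
# Lengths/widths in pixels, curvature as midline arc offset over length,
# angles in degrees, noise sigma in 8-bit intensity units.
regular:
  length: [380.0, 460.0]
  base_width: [70.0, 95.0]
  taper: [0.85, 1.25]
  curvature: [0.0, 0.02]
  angle: [-8.0, 8.0]
irregular:
  length: [360.0, 460.0]
  base_width: [70.0, 100.0]
  taper: [0.85, 1.25]
  angle: [-8.0, 8.0]
  curved_curvature: [0.08, 0.25]
  mild_curvature: [0.0, 0.02]
  branch_point: [0.35, 0.60]
  break_point: [0.50, 0.75]
  type_weights:
    curved: 0.45
    forked: 0.30
    broken: 0.15
    curved_forked: 0.10
# Natural per-root variability applied to every sample, both classes:
# smooth multiplicative width lumps and a gentle midline wiggle.
common:
  width_wobble: [0.04, 0.12]
  midline_wobble: [0.5, 3.0]
render:
  noise_sigma: 6.0
  carrot_rgb: [230, 140, 50]
  background_rgb: [236, 233, 230]
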