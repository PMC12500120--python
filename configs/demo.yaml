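# Minimal end-to-end demonstration: 8 regions, 4 subjects, 3 intensities.
# Durations and grids are deliberately tiny; see configs/study.yaml for the
# full protocol.
out_dir: results/demo
seed: 2024
stages:
  synth: true
  commodels: true
  fit: true
  simulate: true
  phiid: true
  contrast: true
  associate: true
  sweep: true
synth:
  n_regions: 8
  n_subjects: 4
  density: 0.8
commodels:
  normalization: as_printed
  beta_model: distance
hopf:
  duration: 200.0
  trim: 20.0
  band: [0.01, 0.1]
fit:
  truth: {G: 0.16, bias: -0.17, scale: 0.24}
  G_grid: [0.08, 0.16, 0.24]
  bias_grid: [-0.21, -0.17, -0.13]
  scale_grid: [0.16, 0.24, 0.32]
simulate:
  alpha: -1.0
  target: null
  tr: 2.0
phiid:
  tau: 1
contrast:
  measure: redundancy
  scale: absolute
  n_perm: 200
sweep:
  alpha_grid: [-1.0, 0.0, 1.0]
  n_perm: 200
  measure: redundancy
  scale: absolute
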