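# Full synthetic study protocol: 84 regions, 20 subjects, 15-minute
# simulated sessions.  The analysis band is 0.01-0.1 Hz so that the
# oscillators' 0.05 Hz carrier survives filtering (see docs/methods.md).
out_dir: results/study
seed: 7
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
  n_regions: 84
  n_subjects: 20
  edr_lambda: 30.0
  density: 0.35
  subject_jitter: 0.2
commodels:
  normalization: as_printed
  beta_model: distance
hopf:
  duration: 1100.0
  trim: 100.0
  band: [0.01, 0.1]
  kop_band: [0.01, 0.1]
fit:
  truth: {G: 0.16, bias: -0.17, scale: 0.24}
  G_grid: [0.04, 0.08, 0.12, 0.16, 0.2, 0.24, 0.28]
  bias_grid: [-0.25, -0.21, -0.17, -0.13, -0.09]
  scale_grid: [0.16, 0.2, 0.24, 0.28, 0.32]
simulate:
  alpha: -1.0
  target: null
  tr: 2.0
phiid:
  tau: 1
contrast:
  measure: redundancy
  scale: absolute
  n_perm: 1000
sweep:
  alpha_grid: [-1.0, -0.5, 0.0, 0.5, 1.0]
  n_perm: 1000
  measure: redundancy
  scale: absolute
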