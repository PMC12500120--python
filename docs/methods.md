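# Methods

`tusnet` implements, end to end and on synthetic cohorts with known ground
truth, the analysis chain used to study how focal neuromodulation (e.g.
transcranial ultrasound stimulation, TUS) reorganizes higher-order
interactions (HOI) in whole-brain activity: information decomposition of
regional time series, network communication models on structural
connectomes, a calibrated whole-brain oscillator model with a
stimulation-intensity knob, and permutation group statistics.

## Integrated information decomposition (MMI, Gaussian)

For each pair of z-scored regional signals `x, y` we form the 4×4 sample
covariance of `(x_{t−τ}, y_{t−τ}, x_t, y_t)` and decompose the time-delayed
mutual information `I(x_{t−τ}, y_{t−τ}; x_t, y_t)` into 16 atoms on the
product of the two-source partial-information lattice
`A = {{12}, {1}, {2}, {1}{2}}` with itself.  Under the
minimum-mutual-information (MMI) redundancy function for Gaussian
variables, the cumulative informativeness of a node `α→β` is the minimum of
the Gaussian mutual informations between every source collection of `α`
(past) and every target collection of `β` (present); atoms follow by Möbius
inversion along a linear extension of the product order.  Two atoms are
surfaced downstream: persistent redundancy (`{1}{2}→{1}{2}`, "rtr") and
persistent synergy (`{12}→{12}`, "sts").  By construction the 16 atoms sum
to the time-delayed MI; the test suite verifies this conservation to 1e-8
and checks every atom against an independent 16×16 zeta-matrix linear
solve to 1e-10.

Choices:

- **Lag** `τ = 1` sample by default (the minimal-lag convention);
  configurable.
- **Standardization**: each region is z-scored before covariance
  estimation, so all quantities are in nats on a common scale.
- **Regularization**: covariances that are not positive definite (e.g.
  duplicated signals) receive a single diagonal loading of 1e-9 with a
  warning; persistent singularity is an error.
- **Maps**: pairwise rtr/sts matrices are symmetric with undefined (NaN)
  diagonals; per-region strengths are row medians excluding the diagonal;
  ranks are ascending (1 = weakest) with ties averaged.  Region-level
  contrasts are invariant to this direction convention.
- `hoi_matrices` computes one `2N×2N` lagged covariance and slices each
  pair's 4×4 block — numerically identical to the per-pair route (tested)
  and quadratically cheaper.

## Communication models

From a connectome cohort we form representative matrices (cohort mean
normalized by its maximum) and four models: distance (normalized mean
streamline length), shortest-path efficiency `SPE = 1/Λ*` on the cost graph
`L = 1/M̄`, search information
`SI_ij = −log2 Π T` along the stored shortest path (row-normalized
transition matrix, hence asymmetric), and communicability
`CMY = exp(W′)`.  Choices:

- **Strength**: `s_i` is the row strength (sum) of the weight matrix.
- **Communicability normalization**: default `W′_ij = W_ij/(s_i s_j)` as
  the model is usually written in this literature's shorthand; the
  conventional `W_ij/√(s_i s_j)` is available via
  `normalization="symmetric_sqrt"`.
- **Tie-breaking**: Dijkstra with lexicographically-smallest-node-sequence
  tie-break, so the stored geodesic (and therefore SI) is deterministic.
  When several geodesics exist, SI uses the single stored route, not a sum
  over geodesics.
- **Unreachable pairs**: `SPE = 0`, `SI = ∞`; association routines drop
  non-finite entries pairwise and report the count used.
- **Vectors**: `seed_row` extracts the model's row at the stimulated
  target (for change-map associations); `node_summary` takes per-region
  row medians (diagonal excluded), min–max scaled to [0, 1], and is the
  heterogeneity vector β fed to the oscillator model.

## Whole-brain Stuart–Landau model

Each region is a supercritical-Hopf normal form,
`ẋ = (a − x² − y²)x − ωy + GΣ_j M_ij(x_j − x_i) + γη`,
and symmetrically for `y`, integrated with Euler–Maruyama (noise
`γ√dt·N(0,1)` per node and component, initial conditions uniform(−0.1,
0.1)).  Defaults: `f = 0.05` Hz, `γ = 0.02`, `G = 0.16`, `dt = 0.1` s,
1100 s simulations with 100 s trimmed at each end (15 minutes retained).
Heterogeneity and stimulation enter through
`a_i = bias + scale·(β_i + α·[i = target])`, with default
`(bias, scale) = (−0.17, 0.24)` (the distance-model control calibration;
the communicability calibration is `(−0.08, 0.21)`).

- The nonlinearity is the standard normal form `x² + y²`: only this sign
  yields the limit cycle of radius `√a` for `a > 0` that the model's own
  regime description requires.  A variant with the `x² − y²` bracket
  sometimes seen in print is available behind
  `as_printed_nonlinearity=True` for auditing; it does not produce a limit
  cycle.
- The integrator reproduces the analytic radius `√a` to 1% at `dt = 0.1`
  for `a` in the working range (the discrete rotation inflates the radius
  by ≈ `ω²dt/2` per unit `a`, which is within that band for `a ≥ 0.2`).

### Filtering bands

Two bands appear in this literature: an infra-slow "BOLD" band
(0.001–0.01 Hz) and a band containing the oscillators' 0.05 Hz carrier.
`HopfConfig.band` (the output band of `preprocess`) defaults to
0.001–0.01 Hz; `kop_band` (phases/synchrony) defaults to 0.01–0.1 Hz.
Note the infra-slow band *excludes* the model's own carrier: over a
15-minute simulation it carries only ~10 independent samples per pair, so
FC patterns and pairwise information estimates computed there are
statistically empty.  Consequently:

- model **fitting** compares FC and KOP in the synchrony band
  (`kop_band`), and
- the synthetic **study protocol** (`configs/study.yaml`, the ground-truth
  cohorts and intensity sweep) sets the analysis band to 0.01–0.1 Hz.

Both bands remain configurable; the infra-slow default is retained for
`preprocess` so the conventional protocol can be reproduced verbatim.

Simulated cohort series are decimated to a 2 s fMRI-like TR after
filtering (stride subsampling is alias-free below the band edge).  This
matches empirical sampling, conditions the lag-1 covariances (at the 0.1 s
grid neighboring samples are numerically collinear), and shortens the
decomposition.

## Two-stage calibration

Stage one grid-searches the global coupling `G` with homogeneous
`a_i = −0.02`; stage two fixes `G` and searches `(bias, scale)`.  Score:
`r_FC × (1 − |ΔKOP|)` where `r_FC` is the Pearson correlation of
off-diagonal FC triangles and ΔKOP the synchrony gap — both criteria must
be good for a high score, and the product form mirrors how the two fit
measures are usually multiplied in this fitting tradition.  Ties break to the smallest
`G`, then smallest `|bias|`, then smallest `scale`.  A constant β makes
`(bias, scale)` unidentifiable along a ridge and triggers a warning.
Default grids: `G ∈ {0, 0.02, …, 0.3}`, `bias ∈ {−0.3, …, 0.1}` (step
0.01), `scale ∈ {0, …, 0.4}` (step 0.01).

## Group statistics

Regional contrasts use a two-sided label-permutation test on the Welch
t-statistic (groups of unequal size and variance), default 1000
permutations, `p = (1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1)`; each region
has its own spawned permutation stream.  Significance is the per-region
permutation p below 0.05; an optional max-statistic mode provides
family-wise control.  Model–change associations default to Spearman with
Bonferroni correction over 8 tests (4 models × 2 measures per target).

The intensity sweep simulates, for each α on the grid, a fresh control
(α = 0) and stimulated cohort, recomputes the HOI contrast, and records
the Spearman similarity to a reference t-map plus the significant-region
count.  The stimulated site defaults to the mid-heterogeneity region
(β closest to 0.5, `mid_heterogeneity_target`): its control operating
point `bias + scale·β ≈ −0.05` sits near the bifurcation, so the sweep
genuinely carries it from the noise-dominated (α ≪ 0) to the limit-cycle
(α ≫ 0) regime; an arbitrary site with extreme β would traverse only part
of that range and the experiment would change meaning with the random
geometry.  Explicit target indices remain supported.  The sweep contrasts **absolute** median strengths: rank vectors
are permutations of 1..N and therefore zero-sum, so a spatially uniform
shift — exactly what the global regime produces — is invisible on ranks by
construction.  Absolute strengths expose both the localized and the global
regime.

## Synthetic cohort generator

What it emulates: a two-hemisphere 84-region parcellation (34 cortical +
8 subcortical per hemisphere at the default size) with mirrored synthetic
geometry (random points in hemisphere ellipsoids, subcortical nuclei
medial); ~20-subject cohorts of symmetric nonnegative connectomes with
exponential-distance-rule weights (`λ = 30` mm), thresholded to 35% edge
density, Euclidean streamline lengths, and per-subject multiplicative
lognormal jitter (CV 0.2); BOLD-like cohorts generated by the oscillator
model under control (α = 0) and stimulated (α ≠ 0) regimes, one simulation
per connectome with independent seeds.

What it does not emulate: real cortical geometry and tractography,
hemodynamic convolution, session-to-session variability, head motion, and
physiological noise.  Inter-subject variability here comes only from
connectome jitter and simulation noise, so group contrasts are better
powered than on equally sized empirical cohorts; passing tests demonstrate
that the estimators and statistics behave correctly under the model's own
assumptions, not that empirical effect sizes would be detectable at these
sample sizes.  Small parcellations need a higher edge density than the
84-region default to keep the EDR backbone connected (the generator raises
a diagnostic error otherwise); the scaled test protocols use density 0.6
at 20 regions.

## Scaled protocols

The repository's tests and the acceptance script use deliberately reduced
problem sizes chosen once as part of the protocol design: parameter
recovery runs 20 regions / 5 connectomes / 900 s simulations with coarse
grids centred on the default ranges (G step 0.04; bias, scale step 0.04);
the intensity sweep runs 20 regions / 8 subjects per cohort / the full
1100 s protocol at α ∈ {−1, −0.5, 0, 0.5, 1}; the full 84-region study
protocol lives in `configs/study.yaml` and is driven by the numbered
scripts under `analysis/`.

## Known limitations

- The MMI redundancy function is the only one implemented (no CCS/Broja).
- SI uses one stored geodesic; summing over all geodesics would differ on
  graphs with degenerate shortest paths.
- Grid-search calibration only; no gradient-based or Bayesian fitting.
- The G obtained by homogeneous fitting is a proxy: when the target was
  generated heterogeneously, the homogeneous stage's optimum need not
  coincide with the generative G (recovery is tested against
  homogeneously generated targets, matching the staged protocol).
- Permutation p-values are per-region; across-region control is optional
  (max-statistic flag) and off by default.
- The local-to-global regime structure is quantified on the scaled
  20-region protocol, where it is stable across seeds.  At the full
  84-region scale with the default EDR cohort the aggregate coupling per
  node is much larger and the significant-region counts along the α grid
  are scale-dependent and non-monotone (the 84-region driver reports them
  as exploratory output); mapping how the transition depends on network
  size and coupling normalization is open work.
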