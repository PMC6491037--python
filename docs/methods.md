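# Methods

This note documents the models, conventions and design choices behind
`envconn`: what the synthetic generator simulates, exactly how each
pipeline stage is computed, the numerical tolerances involved, and the
limits of what the tests demonstrate.

## Synthetic cohort model

The generator produces source-level ("virtual-sensor") node timeseries
whose band-limited amplitude-envelope correlations are known exactly.
Per frequency band:

* **Envelopes** are lognormal: a latent Gaussian AR(1) process per node
  (autocorrelation time τ = 1 s by default, so envelope dynamics
  survive 1 Hz downsampling) is exponentiated with modulation depth
  σ = 1, giving a stationary positive process with envelope CoV ≈ 1.3 —
  in the range observed for beamformed MEG band envelopes. The latent
  spatial correlation is obtained from the target envelope correlation
  matrix by the Gaussian-copula inversion
  `ρ_latent = ln(1 + ρ_env(e^{σ²}−1))/σ²`, so sampled envelope Pearson
  correlations converge to the requested matrix. Non-positive-definite
  targets (before or after the copula transform) are rejected with an
  error naming the offending band.
* **Carriers** are independent random-phase narrowband noise (white
  noise FFT-masked to the band, unit variance per node), so Hilbert
  envelopes are non-degenerate and carrier phases carry no
  correlation. The per-node band signal is envelope × carrier; bands
  sum per node.
* **Leakage** is a row-stochastic nearest-neighbour blend in node-index
  space: node *i* keeps weight 1−s and spreads *s* equally over its
  index neighbours. This creates zero-lag cross-talk — the signature of
  beamformer leakage — without any forward model. Strength 0 is the
  identity; values in [0, 1) are accepted.
* **Group effects** are additive increments to the envelope correlation
  of chosen (node, node, band) edges in the case group; validity of the
  resulting correlation matrix is checked at design construction.
* **Default base connectivity** is a smooth exponential-decay
  correlation, `ρ_ij = 0.6·e^{−|i−j|/3}` (positive definite as a convex
  blend of a Kac–Murdock–Szegő matrix with the identity). This matters:
  real envelope connectomes have strong reproducible structure, which
  is the premise of rank-based edge masking. With a flat (identity)
  base, the per-cohort rank masks select whichever noise edges happen
  to be high in one cohort, and that selection biases every downstream
  test (family-wise error near 100% in simulation). With structured
  connectivity the masks are signal-driven and both corrected tests
  hold their nominal level.
* **Determinism**: every subject's generator is seeded by
  (design seed, subject index, band index); identical designs
  reproduce cohorts bitwise. An envelope-level shortcut
  (`simulate_envelope_cohort`) samples the 1 Hz envelope process
  directly at the post-trim grid, skipping carrier synthesis — used for
  statistical studies where the raw-timeseries stages are not under
  test.

What the generator does **not** emulate: realistic 1/f spectra, sensor
geometry or forward/inverse modelling, non-stationarity, artifacts, or
phase coupling. Passing tests therefore demonstrate correctness of the
analysis chain under a controlled signal model, not robustness to the
full phenomenology of real MEG.

## Envelope pipeline conventions

* **Epoching**: recordings segment into fixed epochs (2 s typical);
  user-supplied rejection indices drop epochs before concatenation in
  original order. Synthetic data are clean, so rejection is an
  interface, not an algorithm.
* **Band-pass**: zero-phase 4th-order Butterworth (`sosfiltfilt`,
  effective order 8). A linear-phase FIR with the equivalent transition
  band at the 1–4 Hz band and 600 Hz sampling would need thousands of
  taps and dominate pipeline cost; the IIR filter meets the ≥20 dB
  stopband contract verified by the filter-response tests (50 Hz tone
  through the alpha band attenuated ≥20 dB; in-band tone preserved
  within 5% RMS).
* **Symmetric orthogonalization** solves
  `min ‖X − P‖_F` over matrices whose rows are mutually orthogonal
  with free magnitudes, by alternating a polar (SVD) step for the
  orthonormal frame with per-row least-squares scales. Convergence:
  relative objective change < 1e-10 or 200 iterations (non-convergence
  raises a warning). Requires more samples than nodes and full row
  rank; rank-deficient inputs are rejected with the near-duplicate node
  pairs named. The output Gram matrix is off-diagonal zero to ~1e-15
  relative.
* **Envelope conditioning**: running median (window 5 samples at the
  native rate) for despiking, then 1 Hz downsampling as the mean of
  each contiguous one-second window (deterministic and anti-aliasing,
  rather than decimation), then trimming 2 + 3 one-second samples.
  Output length is `floor(duration) − 5` for any duration ≥ 7 s.
* **Coefficient of variation** uses the sample SD (n−1) throughout and
  is exactly invariant to positive rescaling.

## Connectomes, Combined map, masks

* Fisher z values are `atanh(r)`, by default scaled by √(n−3)
  ("variance-normalized", approximately standard normal under
  independence). Since n is constant across edges and subjects, the
  scaling cancels in every downstream statistic (ranks and per-subject
  z-scores are invariant to constant positive scaling); it is exposed
  as a flag for completeness.
* Per-subject z-scoring and all edge statistics operate on the strict
  upper triangle; matrices remain symmetric with a zero diagonal by
  convention.
* The Combined map is computed from the z-scored band maps (matching
  the order of the statistics pipeline); a config switch allows raw
  maps instead. Its valid-edge mask is computed independently by the
  same rank rule, not as a union of band masks.
* Rank masks use ascending mid-rank ties. The retained count is
  `floor(E·(100−pct)/100)` — computed with that exact expression
  because `1 − 0.8` in binary floating point silently loses an edge at
  E = 4005 (800 instead of 801). Boundary ties are all retained, so a
  mask can slightly exceed 20%. Cohort masks are unioned
  ("valid in either cohort"); classification uses a pooled-cohort mask
  (see below).

## Group statistics

* **t-tests** are classic pooled-variance unpaired t, case minus
  control. Edges with zero pooled variance are flagged NaN and excluded
  from correction.
* **Max-statistic correction**: the permutation null of the maximum
  |t| over masked edges; an edge's corrected p is the proportion of
  relabelings whose max |t| reaches its observed |t|. Random
  permutations use the (b+1)/(m+1) convention (p > 0 always); designs
  with no more distinct label splits than requested permutations are
  enumerated exactly, and the tests verify exact agreement with a
  brute-force oracle at 3 vs 3.
* **Cluster test** (network-based statistic): edges with uncorrected
  p < 0.05 form a graph per contrast sign; the statistic is the edge
  count of the largest connected component (node count also reported),
  referred to its own permutation null per sign. An empty graph scores
  size 0, p = 1. Connected components come from
  `scipy.sparse.csgraph`; the test suite checks them against an
  independent breadth-first-search oracle.
* **Sign-consistency filter**: per iteration, half of each group
  (round-half-up: 26 of 51, 54 of 108) is drawn without replacement and
  the sign of the group-mean difference recorded per edge; edges with
  one sign in > 95% of 5000 iterations are flagged. Note this is a
  robustness descriptor, not a calibrated test: under the null the
  subsample difference is centred on the full-sample difference, whose
  sampling noise is comparable to the subsampling noise, so a null edge
  is flagged with probability ≈ P(|Z| > 1.645) ≈ 10% regardless of
  group size. The unit tests assert this analytic behaviour.
* **Activity contrast**: per-node unpaired t on CoV with per-sign
  max-statistic permutation correction at α = 0.025 each (a corrected
  two-tailed 5% test overall). This node-level correction deliberately
  replaces voxelwise TFCE, which belongs to the source-grid stage
  outside this package's scope.
* **Power** uses the noncentral t distribution with
  `ncp = d·√(n₁n₂/(n₁+n₂))`; at d = 0 it returns α exactly and it
  reproduces the classic benchmark power 0.801 at d = 0.5, n = 64 + 64.
  At d = 0.653 with n = 51/108 the standard formula gives ≈ 0.97, a
  known point of divergence from older published power figures for
  these sizes; the implementation follows the standard formula.
* Every stochastic operation takes an explicit seed and records it in
  its result parameters.

## Classification

* Linear SVM (scikit-learn SVC, C = 1 by default; both exposed).
  Features are standardized with training-fold statistics only.
* Balanced LOO: each iteration holds out one random case and one
  random control and trains on `train_per_class` randomly chosen
  remaining subjects per class (guarding against the majority-class
  shortcut in unbalanced cohorts; an internal audit asserts the
  balance). Sensitivity/specificity threshold at decision score 0 (the
  margin boundary); AUC is the trapezoidal area over all pooled
  held-out scores.
* The permutation p rebuilds the null by shuffling labels and re-running
  the cross-validation per permutation; the inner iteration count is
  reducible for desk-scale runs and the p uses (b+1)/(m+1).
* **Known caveat, reproduced as published**: valid-edge masks for
  feature pooling are computed once over the whole cohort *before*
  cross-validation. This avoids selecting features per group (that
  would leak group structure and is rejected by `pool_features`), but
  the mask still sees all subjects. A stricter fold-internal masking
  mode is a possible extension; the pooled behaviour is the documented
  default because it is the published procedure being modelled.
* Transfer: train on all subjects of one cohort, score another over
  the intersection of (band, edge) features; reversed AUC = 100 − AUC
  quantifies opposite-sign expression of the trained effect.

## Problem sizes in the test and acceptance runs

The validation studies run at reduced scale chosen so the full suite
completes in minutes while keeping every contract meaningful: null
calibration uses 200 cohorts of 15 + 15 subjects at 20 nodes with
500-permutation tests on envelope-level simulations; planted-cluster
recovery runs the full raw-timeseries pipeline for 20 cohorts of
51 + 108 subjects at 20 nodes, 40 s, 100 Hz; envelope-recovery uses 50
subjects at 10 nodes, 120 s, 200 Hz. These sizes are the package's own
validation conditions; the pipeline itself handles the full 90-node,
300 s, 600 Hz geometry (the default design), just proportionally
slower.

## Known limitations

* The generator's signal model is a stand-in: no empirical MEG spectra,
  no anatomical leakage geometry, no artifacts. Conclusions about real
  data require real data.
* The sign-consistency filter's ~10% null flag rate (above) means its
  output should be read as a stability ranking, not as inference.
* The HDF5/TSV containers hold dense matrices; at 90 nodes this is
  trivial, but the formats are not designed for thousands of nodes.
* Orthogonalization requires more samples than nodes after epoch
  rejection; very short recordings with large parcellations are
  rejected rather than regularized.
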