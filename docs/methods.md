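# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The generative model behind the synthetic cohort

Real resting-state BOLD cohorts of this design (patient vs control,
~66 subjects, 200 retained volumes at TR = 2 s) cannot be redistributed, so
the package generates cohorts whose statistical structure matches what the
analysis pipeline assumes, with known ground truth at three levels.

**Connectivity states.** Each subject's regional signals follow a
Markov-switching Gaussian process: a hidden chain over `n_states` (default 4)
covariance regimes with self-transition probability `stickiness` (default
0.9, i.e. geometric mean dwell 10 volumes = 20 s) and the remaining mass
uniform. This is the minimal process for which sliding-window k-means is the
natural estimator, making the state decomposition falsifiable by label
recovery. State covariances are random **bipartition sign patterns**:
C = corr(I + g·uuᵀ) with u ∈ {−1,+1}^P and strength g = 1 (off-diagonal
correlations ±0.5) — regions within a block correlate positively, across
blocks negatively, echoing the task-positive/default-mode anticorrelation
structure of real dFC states. Draws whose pairwise Frobenius distance falls
below a floor (¼ of the expected distance for random bipartitions) are
rejected and redrawn. A simpler construction (three modules of 10 regions,
within-module r = 0.5) was evaluated first and discarded: its elbow landed at
k = 5 because only a minority of edges carried state information.

Volumes are drawn as x_t = φ·x_{t−1} + √(1−φ²)·L_{s_t}·ε_t (AR(1) colouring,
φ = 0.1) and band-pass filtered to 0.01–0.08 Hz, matching the preprocessing
the pipeline expects.

**Window mixing is a real limit.** At stickiness 0.9 the mean dwell
(10 volumes) is far below the window length (50), so each window mixes ~5
state visits. Model *selection* still recovers k = 4 robustly (the four pure
regimes anchor the geometry of the pooled window cloud), but window-by-window
label agreement with the majority state saturates near ARI ≈ 0.4 regardless
of state separation — a property of the estimator, not an implementation
artefact. The label-recovery test therefore uses a dwell-dominated regime
(stickiness 0.98, window 20), where sliding-window clustering is consistent
and measured ARI ≥ 0.8.

**Group connectivity effects.** Patient-group state covariances receive
Fisher-z shifts on designated default-mode–sensorimotor edges (default: three
positive shifts and one negative of magnitude 0.5, then a nearest-correlation
repair). Magnitudes are set for detectability at n = 66, not to reproduce any
published t statistics.

**Gradient manifold.** Per network, voxels carry an ascending latent
coordinate on [0, 1]; voxel i's profile over 400 parcels is a Gaussian bump
centred at its coordinate (width 0.08) plus i.i.d. noise (SD 0.25, calibrated
so diffusion embedding recovers the coordinate with |Spearman| ≳ 0.98 — the
module exists to provide a recoverable manifold). Ground truth is
deliberately one-dimensional because only the primary gradient is analysed
downstream. Patient-group shifts add a latent offset (default 0.15) to
designated voxel sets, i.e. an additive profile perturbation that propagates
into a gradient-score displacement.

**Clinical covariates.** Ages are drawn per group (patients 10.41 ± 1.376,
controls 11.28 ± 2.439 years); Wechsler indices and disease duration
(log-normal, median 1 year) are patient-only. Scores reported as
median [IQR] in the motivating cohort were converted to approximate normal
(mean, SD) parameters. Requested gradient–clinical correlations are planted
by mixing the standardized gradient score into the score at weight r. Sex
ratios are free configuration (the motivating report is internally
inconsistent about them) and no demographic test statistic is reproduced.

All randomness fans out from one master seed through `SeedSequence`-derived
per-subject/per-stage streams, so any subset of a run is reproducible.

## Dynamic-connectivity states

- Windows are rectangular (a tapered option exists, off by default), length
  50 volumes, step 1; W = ⌊(T−L)/s⌋+1, which gives 151 windows at T = 200.
  Correlations are clipped to ±(1−10⁻⁷) before atanh; a region constant
  within a window gets zero correlations there (logged).
- k-means uses k-means++ initialisation, 20 restarts, ≤300 iterations,
  Euclidean distance on strict-upper-triangle edge vectors (float32 pooled
  matrix for memory/throughput). Empty clusters are re-seeded at far points
  by the underlying solver.
- The elbow is operationalised as the k maximising the perpendicular distance
  of the (min-max normalised) SSE curve to the chord joining its endpoints.
  Normalisation makes the criterion scale-free; an effectively straight curve
  (normalised distance < 10⁻³) has no elbow and the silhouette argmax is used
  instead, with a logged warning. Silhouette is evaluated on a seeded
  subsample of ≤2000 windows for tractability; Calinski–Harabasz on all.
- Dwell time of a state a subject never visits is NaN and excluded listwise
  from that state's group test.

## Functional gradients

- Row sparsification keeps ⌈density·400⌉ = 40 entries; ties at the threshold
  resolve to the lower column index (deterministic).
- Negative cosine similarities are clipped to 0 before degree normalisation
  (the diffusion operator needs non-negative weights); the clip rate is
  logged. A disconnected affinity graph is an error listing component sizes.
- Embedding: W′ = D^(−α) W D^(−α) with α = 0.5, symmetric conjugate of the
  row-stochastic operator, leading eigenvectors via `eigh`, trivial constant
  vector dropped. With t = 0, component i is scaled by λᵢ/(1−λᵢ) (the
  "automatic diffusion time" convention of the standard gradient toolchain);
  λᵢᵗ scaling is available for t > 0.
- Procrustes alignment is orthogonal only (rotation/reflection after column
  centering, no scaling — downstream z-scoring removes scale anyway and
  scale-free alignment keeps eigenvalue information interpretable). After
  alignment each component's sign is fixed so its correlation with the
  template is non-negative. A rank-deficient cross-product falls back to
  per-component sign matching (logged).
- "Smoothing" of aligned gradients is a deliberate no-op hook: synthetic
  voxels carry no geometry, so no spatial kernel is defined.
- Dispersion is computed both between regions (centroid-to-centroid
  Euclidean distances — the headline metric) and within regions
  (mean voxel-to-centroid distance), in the space of the first 2 gradients by
  default.

## Group statistics

- The adjusted test is an OLS fit of `value ~ 1 + group + age + sex` per
  feature (group and sex coded 0/1), vectorised across features; t is the
  group coefficient over its standard error with n − p df. Without
  covariates this is algebraically the pooled two-sample t (verified to
  10⁻¹⁰ against an independent implementation). A Welch variant is provided
  for the no-covariate case.
- Multiple comparisons: Benjamini–Hochberg step-up for edge/metric families;
  for voxel-level maps, permutation cluster-extent correction — supra-
  threshold voxels at two-sided p < 0.001, chain adjacency within regions,
  null distribution of the maximal cluster size over group-label
  permutations, cluster p = (1 + #{null ≥ size}) / (1 + n_perm). Parametric
  random-field theory is intentionally not implemented: synthetic voxels have
  no smoothness or geometry, and the permutation test is exact under
  exchangeability. The "+1" convention makes the p value valid at finite
  n_perm; size ties make it conservative, never anti-conservative.
  Requesting cluster_p below the resolution of n_perm is an error.
- Clinical correlations are plain Pearson r with p from the t transform at
  n − 2 df, patients-only by default; pairs with n < 4 or zero variance are
  flagged and excluded rather than silently dropped.

## Classification

- Feature assembly: mean aligned z-scored gradient score per selected cluster
  plus the mean windowed-z value per selected edge, 12 + 12 by default;
  fewer candidates than requested is allowed and logged.
- Defaults (none are stated in the motivating design): SVM C = 1, RBF
  γ = "scale", KNN k = 5, 100 trees, boosting depth 3. No class reweighting
  (34 vs 32 is near balanced). Positive class defaults to "patient".
- Standardisation is fit inside training folds only (verified by recording
  fold scaler parameters). LOOCV ROC/AUC is built from pooled decision
  scores, since per-fold ROCs are undefined at test size 1.
- Feature importance is |weight|-based (single fit) or recursive feature
  elimination (refit per round, drop smallest |weight|); RFE is the default
  and is labelled as such — no other importance score is implied.

## Problem sizes used by the test and acceptance runs

The acceptance computation uses 66 subjects, P = 30 regions, T = 200,
windows of 50, k = 2..8 with 20 restarts, majority over 20 master seeds —
a size at which the full selection loop runs in well under a minute per seed.
End-to-end null/power runs use P = 30, 120 voxels per network, 499–1000
permutations, and 3–5 master seeds; calibration suites use 2000 null features
and 200 null datasets. These sizes were chosen so the whole suite runs
comfortably on a single CPU while keeping every Monte-Carlo margin at ≥3
standard errors.

## What passing tests do and do not show

The generator captures the *covariance and manifold structure* the pipeline
estimates, not fMRI physics: no scanner noise model, head motion, spatial
(3-D) geometry, physiological confounds, or inter-site variability. Passing
recovery tests shows the pipeline correctly estimates what it claims to
estimate when the data match its assumptions; it does not validate those
assumptions on real patient data, and no published patient-data result
(group t values, AUCs, clinical correlations) is reproduced or asserted.
Known limitations: window-level state labels are unreliable when dwell times
are shorter than the window (see above); cluster-level inference localises to
clusters, not voxels; and feature selection and cross-validation share the
cohort, so reported in-cohort AUCs under planted effects are optimistic —
the permutation-null check quantifies exactly this.
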