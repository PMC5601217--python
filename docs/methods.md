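# Methods

## The analysis model

`neocca` implements a multimodal association analysis for cohort imaging
studies. The data are (1) several *modality blocks* — subject × voxel
matrices of aligned, smoothed maps (volumetric Jacobian or intensity maps,
diffusion skeletons) sharing a subject set; (2) a mixed clinical covariate
table; (3) outcome scores with partial follow-up. The chain is:

1. **Clinical encoding.** Continuous variables are z-scored; binary
   indicators are centered (optionally fully standardized). Missing entries
   are imputed (mean for continuous, mode for binary) and counted. The
   encoded matrix X must be complete and full rank.
2. **Linked decomposition.** Each block is variance-normalized (voxels
   centered across subjects, block scaled to total variance 1) so
   modalities with different units and smoothness weigh equally. Blocks are
   concatenated feature-wise, whitened to at most `max_components`
   principal dimensions, and rotated by a fixed-point ICA contrast
   (logcosh, deflation) toward spatially independent sources. Every
   component is a set of per-modality maps (least-squares regression of
   each block on the courses) tied to one unit-variance subject course.
   Components are ordered by explained-variance share; those below a
   rejection threshold are flagged and excluded from the exported feature
   matrix Y.
3. **CCA.** Solved in closed form: with orthonormal bases Q_x, Q_y of the
   centered blocks, the SVD of Q_x′Q_y gives canonical correlations
   r_1 ≥ … ≥ r_m and weights a, b scaled to unit-variance variates
   U = X_c a, V = Y_c b. Loadings are marginal correlations of each
   original variable with its own-side variate.
4. **Inference.** Pair significance: rows of X are permuted against Y; each
   refit's *maximum* canonical correlation forms a single null, and
   p_k = (1 + #{max_r ≥ r_k})/(P+1). This gives monotone p-values across
   pairs and family-wise control over the sequence. Loading significance
   uses the analogous max-|r| null over the variables of a block
   (per-variable nulls switchable). Confidence intervals are percentile
   bootstrap over subject resamples, with each replicate's pairs greedily
   re-matched (by |corr| between replicate and original variates, both
   evaluated on the original subjects) and sign-aligned before
   accumulation; the fraction of replicates needing reordering or flips is
   reported as a diagnostic.
5. **Voxel maps.** Per modality, each voxel's loading r(v) on a chosen
   imaging variate is converted to t = r√((n−2)/(1−r²)) and corrected for
   family-wise error by the max-|t| permutation scheme (per modality by
   default, jointly across modalities by switch).
6. **Outcome regression.** Each outcome score is regressed on each leading
   imaging variate over complete cases; F = (n−2)R²/(1−R²) with df
   (1, n−2), plus the value recomputed under a (1, n−1) denominator-df
   convention, since published tables sometimes print that df pair.
   Bonferroni correction over the variates × outcomes grid is the default
   (Holm and Benjamini–Hochberg available).

## Parameters that matter

| parameter | default | why |
|---|---|---|
| `max_components` | 100 (library), 20 (pipeline) | must stay below n; pipelines on simulated data use 20 because simulations plant ≤8 components |
| component rejection threshold | 1e-4 EV share | separates estimated components from the whitening noise floor in high-SNR data; for small simulated component counts the EV gap is orders of magnitude wide and 1e-2 is used |
| `P` permutations | 10,000 | permutation floor 1/(P+1) ≈ 1e-4; tests use 100–1,000 |
| `B` bootstrap | 10,000 | percentile CIs; tests use 200–500 |
| α (pairs / maps) | 0.05 / 0.01 | conventional levels |
| ridge regularization | 0 (off) | intended regime is n ≫ p, K; ridge exists for rank-deficient sensitivity runs |

## Numerical choices

- Rank decisions use a relative singular-value cutoff of 1e-10; a
  rank-deficient block without regularization is an error naming the block.
- CCA sign convention: each pair is flipped so the clinical variable with
  the largest |loading| loads positively. ICA component signs are fixed so
  the largest-|entry| spatial-map value is positive.
- p-values use the add-one estimator (c+1)/(P+1): strictly positive, valid,
  and its floor at P = 10,000 is 0.0001.
- **ICA rotation subspace.** The independence rotation is restricted to
  principal dimensions whose eigenvalue share exceeds a floor (default
  1e-4). After whitening, noise-floor dimensions have unit variance and are
  Gaussian to first order; an ICA rotation there is unidentifiable and in
  practice smears planted signal variance across many components. Those
  dimensions are therefore retained as unrotated principal components and
  are the natural targets of rejection. `converged` reflects whether the
  fixed-point iteration hit its cap.
- Degenerate bootstrap resamples (rank loss) are dropped and counted; more
  than 10% dropped is a hard error. Zero-variance voxels/variables yield
  NaN markers, are counted, and are excluded from max statistics.
- Perfect fits report infinite t/F markers with floored p-values.

## What the generator emulates — and what it does not

The generator reproduces the statistical structure the analysis assumes:
K standard-normal latent subject courses; per-modality spatial maps built
as disjoint contiguous blobs (spatial independence by construction),
Gaussian-smoothed (σ = FWHM/√(8 ln 2), one pass) and unit-normed; blocks
Y_m = s_m·Z·A_mᵀ + E_m with i.i.d. noise, smoothed at the modality's FWHM
and rescaled to its nominal sd when smoothing is on. Clinical links are
linear: a linked continuous variable is s·Z_j + √(1−s²)·ε, so with one
linked variable per latent the population canonical correlation of pair j
is exactly s. Binary factors threshold a latent normal at the
prevalence-matching quantile; in the default study configuration binary
factors are unlinked, so thresholding attenuation cannot blur the planted
canonical levels. Outcomes are 100 + 15(effect·variate + √(1−effect²)·ε)
with proportional missing follow-up (24 of 449).

The default `study_spec` mirrors the cohort the pipeline is designed
around: 449 infants; 4 modality blocks (two smoothed volumetric, two
skeleton); 7 continuous + 25 binary clinical factors with the cohort's
prevalences (from <1% to ~65%); one missing parenteral-nutrition entry;
planted canonical correlations (0.9, 0.7, 0.5); noise sd 0.02 per voxel
against unit-norm signal maps, chosen once as a moderate-noise setting.

Not emulated: registration error, scanner artefacts, lesion pathology,
spatially inhomogeneous or non-Gaussian noise, nonlinear
clinical-imaging links. Passing recovery tests therefore demonstrates the
estimation machinery under the model's own assumptions, not robustness of
those assumptions to real MRI data. The spatial covariance of real
modality noise is unknown; i.i.d.-then-smoothed noise is an assumption of
convenience.

## Design choices where the design was open

- **Decomposition substitute.** The full variational-Bayes linked ICA
  (modality noise precisions, ARD priors) is deliberately not reproduced;
  the deterministic PCA + FastICA pipeline honors the same contract
  (shared courses, per-modality maps, rejection of unsupported components)
  and keeps every downstream stage exactly testable. Explained-variance
  rejection replaces ARD, which has no meaning outside the Bayesian fit.
- **Sequential pair testing** is read as one max-correlation null shared by
  all pairs (monotone p-values follow); a step-down variant that
  residualizes preceding observed variates is available via
  `method="stepdown"` but off by default.
- **Permuting the clinical block** (rather than imaging) is arbitrary but
  fixed and logged; the test is statistically identical either way.
- **Percentile bootstrap** (not BCa): simplest estimator consistent with
  asymmetric intervals that may sit below the point estimate; containment
  of the point estimate is *not* forced, and alignment diagnostics are
  surfaced instead.
- **Binary columns centered, not scaled,** by default (prevalence retained
  in the column scale); full z-scoring is a switch, since either choice is
  defensible and the difference is a per-column affine map that leaves
  canonical correlations unchanged.
- **Component order into CCA** is by explained variance; CCA is invariant
  to column order of Y.
- **Recovery analyses** (the end-to-end planted-structure check) run the
  pipeline with the ≥10% prevalence filter and rejection at the EV gap
  (1e-2): with ~25 pure-noise binary columns retained, the intrinsic
  upward bias of sample canonical correlations at n=500 can reach ~0.1 on
  the third pair — a property of the estimator, reproducible by fitting
  CCA directly against the true latents, not of the pipeline.

## Problem sizes used by tests

Simulation-based checks run at deliberately modest scale: grids 6³–16×16×8,
n = 60–500 subjects, P = 100–10,000 permutations, B = 200–500 bootstrap
replicates, 40–300 replicate simulations per calibration. These sizes make
Monte-Carlo bounds (type-I error in [0.02, 0.09] at nominal 0.05, coverage
95% ± 5%, blob sensitivity ≥ 80%) tight enough to catch convention errors
(wrong p-value estimator, missing alignment, wrong df) while the whole
suite stays fast.

## Known limitations

- The decomposition substitute has no per-subject modality weighting and no
  posterior noise model; heteroscedastic modalities are handled only by the
  global variance normalization.
- Mean/mode imputation is only sensible for near-complete covariates (the
  intended regime, ≤1 missing case per variable); no multiple imputation.
- The max-statistic loading test is conservative for weak variables inside
  a block containing very strong ones.
- Bootstrap pair alignment can fail silently in principle when two
  population canonical correlations are exactly tied; the reorder/flip
  diagnostics are the guard.
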