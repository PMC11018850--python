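# Methods

This note documents the models, numerical choices and known limitations of
`smfdx`. It is the package's own account of its science; every number it
mentions is computed by the test suite or by `scripts/acceptance.py`.

## The problem

A serum metabolic fingerprint (SMF) is the vector of aligned *m/z* feature
intensities extracted from one serum mass spectrum (MALDI-TOF–style, singly
charged ions, metabolite range 100–1000 Da). The diagnostic task is
two-class: endometrial cancer (EC) versus non-cancer controls with abnormal
ultrasound findings (Non-EC). The pipeline turns raw profile spectra into
fingerprints, learns a classifier, and distills a small metabolite panel
(glutamine, glucose, cholesterol linoleate) whose logistic probability —
the Met-score — is the deployable diagnostic, optionally combined with the
clinical marker CA-125.

## Synthetic cohorts

`smfdx.synth.generate_cohort` emulates the statistical structure the
analysis assumes. Per sample *i* and feature *j*:

```
apex_ij = mean(group_i, j) · scale_i · F_ij · D_ij
profile_i(mz) = baseline(mz) + Σ_j apex_ij · N(mz; mz_j·(1+δ_i), σ_peak) + ε
```

* **Feature positions**: 272 quasi-regular positions over 100–1000 Da
  (even spacing ± 30% jitter, guaranteeing resolvability at the configured
  peak width). Planted differential features can be pinned to specified
  *m/z* values — the pipeline pins them to the [M+H]⁺/[M+Na]⁺/[M+K]⁺ adduct
  masses of the three panel metabolites so the annotation stage is
  exercised end-to-end.
* **Base intensities**: log-uniform on [50, 2000] arbitrary units;
  planted markers are drawn from the upper range (≥ 300) — a marker the
  mean-intensity screen (Ī ≥ 100) could never see would not be a usable
  biomarker, so the generator plants screenable ones.
* **Class effects**: the EC mean of a differential feature is the base
  intensity times 2^(log2 effect); default three markers with effects
  (+1, +1, −1) — two up-regulated, one down-regulated.
* **Technical variation** `F_ij`: multiplicative log-normal with
  sd/mean = `technical_cv` (default 0.10), mean-preserving
  (σ² = log(1+cv²), centered at −σ²/2). This reproduces the ~10% median
  per-feature CV regime of well-behaved particle-assisted LDI measurements.
* **Baseline**: amplitude·exp(−decay·(mz−mz_min)), default 100·exp(−0.01·Δmz)
  — the low-mass matrix hump; any smooth positive baseline exercises the
  correction.
* **Noise** ε: additive Gaussian (default sd 1), profile clipped at 0.
* **m/z jitter** δ_i: one relative (ppm) shift per sample (default off;
  50 ppm in the pipeline), making alignment nontrivial but controllable.
* **Dropout**: each true peak absent with probability `dropout_prob`,
  exercising the presence filter and imputation.
* **Covariates**: age, BMI, CA-125, menopause, diabetes, stage. CA-125 is
  always mildly class-associated (log-normal, AUC ≈ 0.65–0.75 — the
  clinical-baseline regime); age is class-independent unless
  `confound_age` shifts the EC group by +7 years. Menopause is derived
  from age (with 10% flips), so age confounding propagates realistically.

What the generator does **not** emulate: isotope envelopes, ionization
suppression, detector saturation, mass-dependent resolution, correlated
biological covariance between metabolites, batch effects. Passing tests
demonstrate the statistical machinery is correct under the stated model;
they do not certify performance on real instrument data.

The calibration generator produces replicate intensities on a line
(default slope 6 per µM, noise sd 1 → LOD ≈ 0.5 µM, the regime of a good
small-metabolite assay).

## Preprocessing

* **Baseline**: morphological opening (erosion+dilation, flat window of
  2·half_window+1 = 101 grid points ≈ 5 Da at the 0.05 Da default grid),
  lightly mean-smoothed; subtract and clip at 0. The opening tracks any
  smooth baseline and ignores peaks narrower than the window.
* **Smoothing**: Savitzky–Golay, window 9, order 3 — peak-shape
  preserving (exact on polynomials up to the order).
* **Peak picking**: local maxima of the smoothed signal with
  S/N ≥ 3. The S/N numerator is apex height above the local median — the
  opening baseline sits at the noise's *lower envelope*, so the corrected
  noise floor retains a positive offset (~1.5σ) that a plain apex/noise
  ratio would count as signal. The noise scale is estimated on the
  corrected but **unsmoothed** spectrum (smoothing shrinks apparent noise
  ~2.3×, which would silently turn an S/N 3 rule into S/N ≈ 1.3), as the
  blockwise upper-quartile spread (q75−q50)/0.6745 of a Savitzky–Golay
  high-pass residual, divided by the filter's known white-noise
  attenuation. The quartile spread (unlike the windowed MAD) survives both
  ~45% in-peak grid occupancy at 272 peaks/900 Da and the zero-clipping of
  near-empty spectral regions. Apex position and height are refined by a
  3-point parabola, removing the ±half-grid-step quantization that would
  otherwise dominate ppm errors at low *m/z*.
* **Alignment**: peaks pooled over samples, sorted, greedily clustered; a
  feature grows while the next peak is within `tolerance_ppm` (default
  300 ppm) of the running intensity-weighted consensus. One peak joins at
  most one feature; duplicate peaks from one sample keep the most intense.
* **Presence filter**: a feature is retained iff detected in ≥ 2/3
  (inclusive) of the samples of **at least one** group — the OR reading,
  so group-specific markers survive; an AND reading would discard a marker
  absent in controls, which is exactly the interesting case.
* **Matrix**: missing entries imputed as zero by default (absence of a
  fingerprint peak is informative); half-minimum available. Optional TIC
  (total ion current) row normalization, off by default.
* **Standardization**: per-feature z-scores with mean/sd (ddof 0) learned
  on a designated training subset only; zero-variance features dropped
  with a warning; parameters stored for held-out reuse. Inside
  cross-validation the standardization is refit per training fold.

## QC statistics

* **CV**: 100·sd/mean per feature across replicates, sd with ddof 1;
  zero-mean features excluded with a warning. Scale-invariant by
  construction.
* **Similarity blueprint**: cosine similarity between sample fingerprints
  over unordered within-group pairs. Two modes: `centered=True` (adjusted
  cosine — each feature mean-centered across the cohort; shift-invariant,
  self-similarity 1) and `centered=False` (plain cosine of raw
  fingerprints). For replicate-like data the raw-profile mode is the one
  that produces the familiar "~95% of pairs above 0.85" picture, because
  the shared mean profile dominates; after per-feature centering,
  technical replicates are near-orthogonal and pairwise scores scatter
  around 0 — the two modes answer different questions, and the pipeline
  reports the raw-profile frequencies.
* **Calibration / LOD**: OLS of mean intensity versus concentration; σ is
  the sd of the individual replicate residuals about the fitted line
  (dof N−2) — the method sd, which does not shrink with the replicate
  count as the sd of level means would; LOD = 3σ/S, undefined (NaN,
  flagged) when the fitted slope is ≤ 0.

## Classification

* **LASSO** = L1-penalized logistic regression; the penalty λ (default
  0.6, the analysis' operating value) maps to scikit-learn's C = 1/λ,
  liblinear solver, fixed random state for determinism. Plain logistic is
  ridge (C = 1); PLS-DA uses 2 components on a 0/1 response; random
  forest 100 trees; decision tree default depth. Scores are positive-class
  probabilities (PLS: the continuous prediction).
* **Repeated CV**: stratified 5-fold, 20 repeats; fold seeds derived
  deterministically from one master seed (blake2s of (seed, tag)); the
  final model is refit on the full discovery matrix for validation-cohort
  evaluation.
* **LASSO score** (the per-feature quantity used by the panel screen):
  mean |standardized coefficient| over all CV fits — selection stability ×
  magnitude. It is 0 for never-selected features and grows with both
  selection frequency and effect size.
* **ROC/AUC**: midrank Mann–Whitney probability (equal to the trapezoidal
  area of the full ROC curve; verified against brute-force pairwise
  concordance). DeLong structural components give the AUC variance, the
  95% CI (normal approximation, clipped to [0,1], collapsed and flagged
  when degenerate) and the two-sided paired test; identical classifiers
  give p = 1 by convention.
* **Youden point**: maximizes sensitivity+specificity−1 over the ROC
  thresholds; ties break toward higher sensitivity.
* **Permutation test**: labels permuted, the *entire* CV pipeline
  (including in-fold standardization) rerun per permutation;
  p = (1+#{perm ≥ obs})/(B+1). Note a discreteness caveat: under the null
  the LASSO statistic frequently ties at AUC 0.5 exactly (all-zero fits),
  making the test conservative; calibration checks therefore use the
  continuous ridge-logistic statistic, while the conservative behaviour of
  the LASSO version only ever overstates p (never understates).

## Panel

* **Screen**: Ī ≥ 100, direction-agnostic univariate AUC
  (max(a, 1−a)) ≥ 0.70, LASSO score ≥ 0.01 — all inclusive, all on raw
  intensities.
* **Annotation**: theoretical adduct m/z = monoisotopic mass (pyteomics)
  + cation mass − electron mass (the electron matters: 0.55 mDa is
  several ppm below m/z ~180); annotation kept iff
  |observed−theoretical|/theoretical·1e6 < 3 ppm. The bundled formula
  table is a curated list (3 panel metabolites + ~23 common serum
  metabolites as decoys), not a metabolome database; user tables are
  accepted. In the synthetic pipeline the "accurate mass" is the
  generator's exact peak position, standing in for a high-resolution
  read-back.
* **Met-score**: logistic probability over the three metabolite
  intensities (adduct forms summed per metabolite), standardized with
  training statistics; combination with CA-125 is a second two-covariate
  logistic. Both use a very weak ridge (C = 1e4) purely for numerical
  stability.
* **Clustering accuracy**: Ward agglomerative clustering (k = 2) of
  z-scored panel intensities; clusters mapped to labels by the better of
  the two assignments, so chance level is ~0.5 and the result lies in
  [0.5, 1].
* **Covariate screen**: Firth bias-reduced logistic regression of the
  label on Met-score + standardized covariates, Wald odds ratios and
  p-values. Firth (Jeffreys-penalized Newton) is used because a strong
  Met-score often separates the classes, where plain maximum likelihood
  diverges; under separation Firth estimates stay finite and the screen's
  covariate inference remains usable. Constant covariates are dropped
  with a warning; near-collinear pairs (|r| > 0.999) raise an error.

## Power analysis

From a pilot matrix: per-feature Cohen's d (pooled sd, ddof 1) and a
Storey null-proportion estimate π₀ = #{p > 0.5}/(0.5·m) capped at 1. For
the power curve the smallest-|d| π₀-fraction of features is treated as
null (d = 0); cohorts are resimulated as unit-variance normals with those
effects; per-feature two-sample t-tests are corrected by
Benjamini–Hochberg at the target FDR (default 0.1); predicted power is the
mean true-positive rate among non-null features, with its Monte-Carlo se.
Optional winsorizing of |d| at its 95th percentile curbs pilot
over-optimism. Sanity anchors: with a single feature the BH step at level
q is exactly the t-test at α = q (verified against the closed noncentral-t
power), and power is non-decreasing in n within Monte-Carlo error.

## Orchestration and problem sizes

`smfdx.pipeline.run_pipeline` executes simulate → preprocess → qc → train →
evaluate → panel → power from one config; a master seed fans out to
per-stage seeds through a fixed hash derivation, so toggling stages never
changes another stage's draws. The acceptance script runs a 100-per-group
cohort with a 60/40 stratified discovery/validation split, 5×20 CV for all
five models, a 199-permutation test (single-repeat CV statistic), a
10-replicate QC cohort and a 6+6 pilot for power — sizes chosen so the
whole run completes in well under a minute while keeping every estimate's
Monte-Carlo error small relative to the effects of interest. Tests use
smaller cohorts of the same structure; matrix-level tests draw the
generator's realized intensities directly (`GroundTruth.to_feature_matrix`)
and skip spectrum rendering.

## mzML support

The environment's mzML readers were not usable as installed, so
`smfdx.io_mzml` implements a minimal, documented subset of mzML 1.1
(single MS1 spectrum, 32/64-bit float arrays, none/zlib compression,
standard cvParam accessions) with stdlib XML tooling. It round-trips the
package's own files and reads files that follow the same subset; it is not
a general mzML implementation.

## Known limitations

* The generator's independence assumptions (features independent given
  class; noise homoscedastic) are optimistic relative to real serum data;
  cross-validated AUCs on synthetic cohorts with planted |log2 effect| = 1
  are accordingly near-perfect.
* DeLong CIs are asymptotic; at very small n or AUC near 1 they clip and
  can undercover.
* The permutation test with the LASSO statistic is conservative under the
  null (tie mass at AUC 0.5).
* The power module resimulates from normal theory rather than resampling
  pilot spectra; heavy-tailed intensity noise would make it optimistic.
* Firth inference uses Wald p-values; penalized-likelihood-ratio p-values
  would be more accurate at extreme odds ratios.
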