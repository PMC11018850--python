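# smfdx — serum metabolic fingerprint diagnostics

`smfdx` is a tested, reusable implementation of a serum-metabolic-fingerprint
(SMF) diagnostic workflow of the kind used to discriminate endometrial cancer
(EC) from non-cancer controls with abnormal ultrasound findings (Non-EC).
It takes raw MALDI-TOF–style profile spectra (one per serum sample) through:

1. **Preprocessing** — morphological baseline correction, Savitzky–Golay
   smoothing, S/N ≥ 3 peak picking against a robust local noise estimate,
   ppm-tolerance peak alignment across samples, a ≥ 2/3 within-group presence
   filter, and z-score standardization learned on training samples only.
   The result is the fingerprint matrix: samples × aligned *m/z* features.
2. **QC** — per-feature coefficient-of-variation (CV = 100·sd/mean)
   distributions over technical replicates, the within-group pairwise
   cosine-similarity blueprint, and calibration linearity with the limit of
   detection LOD = 3σ/S (σ the method sd, S the calibration slope).
3. **Classification** — five model families (L1-penalized "LASSO" logistic,
   ridge logistic, PLS-DA, random forest, decision tree) under repeated
   stratified 5-fold cross-validation (20 repeats by default) with
   standardization refit inside every training fold; ROC curves with DeLong
   variance (95% CIs, paired DeLong test against the CA-125 clinical
   baseline), Youden-index operating points, fixed probability cutoffs, and
   a label-permutation test of model validity,
   p = (1 + #{perm AUC ≥ observed}) / (B + 1).
4. **Panel selection** — candidate features screened on mean intensity
   Ī ≥ 100, direction-agnostic univariate AUC ≥ 0.70, and LASSO stability
   score ≥ 0.01; accurate-mass annotation against a curated formula table
   over [M+H]⁺/[M+Na]⁺/[M+K]⁺ adducts within 3 ppm; adduct intensities
   summed per metabolite; the **Met-score** (logistic probability over the
   three panel metabolites — glutamine, glucose, cholesterol linoleate) and
   its logistic combination with CA-125; Ward-clustering accuracy; and a
   Firth-logistic odds-ratio screen for covariates (age, BMI, diabetes,
   menopause).
5. **Power analysis** — pilot-based per-feature effect sizes (Cohen's d)
   with a Storey null-proportion estimate, resimulated under
   Benjamini–Hochberg control at FDR 0.1 to give predicted power per
   per-group sample size.

A first-class synthetic-cohort generator (`smfdx.synth`) emulates the data
structure the analysis assumes — 272 metabolite peaks in 100–1000 Da, two
classes with a handful of planted up/down-regulated markers, ~10% technical
CV, an exponentially decaying baseline, additive noise, per-sample ppm
jitter and peak dropout — so the entire pipeline is testable without any
instrument data.

## Worked example

```python
import numpy as np
from smfdx import synth, preprocess, classify, panel
from smfdx.pipeline import panel_adduct_mzs

# simulate 30 + 30 serum spectra; the six planted differential features sit
# at the adduct masses of glutamine, glucose and cholesterol linoleate
mzs, effects = panel_adduct_mzs()
cfg = synth.CohortConfig(n_per_group=30, n_features=272,
                         n_differential=6, differential_mzs=tuple(mzs),
                         log2_effect_sizes=tuple(effects),
                         mz_jitter_ppm=50.0, dropout_prob=0.05, seed=42)
spectra, truth = synth.generate_cohort(cfg)
matrix = preprocess.preprocess_cohort(spectra, truth.manifest)
print(f"{matrix.n_samples} samples x {matrix.n_features} aligned m/z features")

result = classify.repeated_cv(matrix, classify.ModelConfig(
    algorithm="lasso", l1_penalty=0.6, n_folds=5, n_repeats=20, seed=0))
print(f"cross-validated AUC: {result.mean_auc:.3f} "
      f"({result.selected_feature_count} features in the final model)")

for c in panel.screen_candidates(matrix, result):
    j = np.argmin(np.abs(truth.true_feature_mzs - c.feature_mz))
    c.accurate_mz = float(truth.true_feature_mzs[j])   # high-res read-back
    panel.annotate_by_mass(c)
    best = c.annotations[0]
    print(f"  m/z {c.feature_mz:9.4f}  I={c.mean_intensity:7.1f} "
          f"AUC={c.univariate_auc:.2f} score={c.lasso_score:.3f}"
          f"  -> {best.name} {best.adduct}")
```

prints

```
60 samples x 272 aligned m/z features
cross-validated AUC: 0.985 (6 features in the final model)
  m/z  671.5700  I=  936.1 AUC=1.00 score=3.183  -> cholesterol linoleate [M+Na]+
  m/z  687.5456  I=  498.3 AUC=0.97 score=0.751  -> cholesterol linoleate [M+K]+
  m/z  169.0581  I= 1005.9 AUC=0.97 score=0.414  -> glutamine [M+Na]+
  m/z  219.0260  I=  495.3 AUC=0.93 score=0.254  -> glucose [M+K]+
  m/z  147.0762  I=  545.6 AUC=0.93 score=0.170  -> glutamine [M+H]+
  m/z  203.0519  I=  849.7 AUC=0.94 score=0.164  -> glucose [M+Na]+
```

All 272 planted features were recovered by alignment; the screen returns
exactly the six planted adduct features, and the mass annotation maps them
back to the three metabolites. (The univariate AUCs and the cross-validated
AUC are high here because the planted |log2 effect| of 1 at 10% technical CV
is a strong signal at n = 30 + 30.)

## Command line

The `smfdx` tool wraps the library:

```sh
smfdx simulate --n-per-group 50 --seed 1 --out spectra/
smfdx preprocess --spectra spectra/ --manifest spectra/manifest.csv \
    --snr 3 --tolerance-ppm 300 --out out/
smfdx qc cv --matrix out/feature_matrix.csv --out cv.csv
smfdx train --matrix out/feature_matrix.csv --algorithm lasso --l1 0.6 \
    --folds 5 --repeats 20 --seed 1 --out model.json
smfdx evaluate --model model.json --matrix validation_matrix.csv
smfdx panel --matrix out/feature_matrix.csv --model model.json \
    --i-min 100 --auc-min 0.70 --score-min 0.01 --ppm 3 --out panel.csv
smfdx power --pilot-matrix pilot.csv --fdr 0.1 --n-grid 25,50,100,200 \
    --sims 200 --seed 1 --out power.csv
smfdx run --outdir run/ --seed 1          # the whole pipeline
```

Spectra are read as two-column (m/z, intensity) text or mzML; matrices and
reports are plain CSV/JSON.

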