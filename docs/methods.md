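# Methods

## Model and pipeline

`neurodc` analyses a two-group resting-state fMRI cohort in five
stages.

**Degree centrality.**  Per subject, the in-mask voxel time series form
the nodes of a functional connectivity graph whose edges are Pearson
correlations.  The weighted degree of voxel i sums the correlations
exceeding a threshold r0 (`Dc(i) = Σ_{j≠i} r_ij, r_ij > r0`); the
binary variant counts them.  Negative edges are excluded by
construction because r0 must be positive.  The correlation matrix is
processed in row chunks and never materialised, with a contractual
1e-10 agreement against the dense computation.  r0 defaults to 0.25,
the convention of the voxel-wise DC literature and of common
preprocessing toolboxes; the source analysis does not state its value,
so it is configurable and recorded in all outputs.

**z transformation.**  Two readings of "transform to a z-score map" are
supported: `map_standardize` (default) z-scores the finished degree map
across in-mask voxels, yielding the per-subject zDC maps whose region
means are the downstream features; `fisher_rz` instead applies atanh to
each suprathreshold correlation before summation (r clipped to
±(1−1e-7)).  The source text does not disambiguate; both are first-class
options.

**Smoothing.**  The z map is scattered to the full grid, convolved
separably with an isotropic Gaussian (sigma = FWHM / (2√(2 ln 2)) per
axis, converted to voxel units; kernel radius 8 sigma so truncation
error is ~1e-14; zero padding), then re-masked.  Mass therefore leaks
across the mask edge, matching common volumetric-smoothing behaviour; a
mask-renormalised variant (divide by the smoothed mask indicator) is
available by flag.  FWHM defaults to 6 mm at 3 mm voxels.

**Feature extraction.**  One value per atlas region: the arithmetic
mean of smoothed zDC over the region's in-mask voxels, in region-id
order.  Labels are MCI iff MoCA < 26, strictly (26.0 is nMCI).  Feature
tables are stored at 10 significant digits — values are quantised at
construction so TSV round-trips are bit-exact.

**Selection.**  Stage 1 iteratively removes one member of the
most-correlated feature pair (the member with the larger mean absolute
correlation against all other retained features; ties drop the earlier
column) until no retained pair exceeds the 0.75 threshold; a
single-pass variant is available.  Stage 2 fits an L1-penalised
logistic model per penalty on the grid 10^-6…10^3 step 10^0.2 (46
points), with stratified 10-fold CV scored by the pooled MSE between
held-out predicted probabilities and the 0/1 labels.  "L1 logistic
scored by MSE" honours both halves of an ambiguous protocol description
(logistic selection; MSE cost); a plain linear-lasso-on-labels mode is
behind a flag.  Features are z-standardised inside each training fold
only, so the penalty is scale-equitable without leakage.  The penalty
maps to scikit-learn's parameterisation as C = 1/(n·alpha) (per-sample
mean loss).  Ties on the CV criterion go to the larger penalty (the
sparser model); refit coefficients with |w| > 1e-8 count as nonzero.

**Classification.**  Linear-kernel SVM (linearity is required for the
per-feature weight reporting), random forest and logistic regression,
evaluated by leave-one-out CV: each subject is predicted by a model
fitted on the other n−1, including training-only standardisation and an
inner stratified 5-fold, accuracy-scored grid search (SVM/LR: C in
{0.01, 0.1, 1, 10, 100}; RF: 100/500 trees × depth ∅/3/5).  The inner
search is hand-rolled (same folds, same first-best tie-break as the
standard implementation) because framework overhead per search
otherwise dominates millisecond fits inside LOOCV.  Scores are the
signed margin (SVM) or class-1 probability (RF/LR); hard labels use
sign / 0.5.  The single pooled ROC over all held-out scores gives the
AUC, which equals the Mann-Whitney U statistic divided by
n_pos·n_neg (ties count one half).  Cohen's kappa is computed in closed
form from the confusion table, with kappa ≡ 0 when chance agreement is
1.  The permutation test shuffles labels, re-runs the full LOOCV (and,
when nested selection is enabled, the pruning + LASSO stage per
permutation), and applies the add-one rule
p = (1 + #{perm ≥ observed}) / (B + 1); the statistic is AUC by
default, accuracy by flag.  The study-scale protocol uses 5000
permutations; desk-scale runs default to none and calibration
experiments use 99.

**Demographics.**  Continuous variables are screened with a one-sample
KS test against a Normal with the sample's own mean/SD.  This is the
uncorrected KS (as common statistics packages apply it), which is
anti-conservative when parameters are estimated; a Lilliefors-corrected
variant is behind a flag.  Both groups normal (p > 0.05) routes to the
pooled two-sample t-test (Welch by flag), otherwise to the Mann-Whitney
U (exact for tie-free samples of ≤ 20, asymptotic with tie correction
otherwise).  Dichotomous variables use the Yates-corrected chi-square
(uncorrected and Fisher-exact variants by flag); Yates reproduces the
published sex-distribution p-value exactly.  The summary-level t-test
(from n, mean, SD) is exact: it agrees with the full-data test to
1e-12 when given that data's moments.

## Synthetic cohorts

The generator emulates *already preprocessed* band-limited BOLD data.
Each atlas region r carries a latent signal s_r(t) (iid Gaussian by
default; an optional 0.01–0.08 Hz Butterworth band-pass at TR = 2 s
shapes the spectrum, off by default since DC depends only on
correlation structure), and voxel v in region r has

    x_v(t) = w_r · s_r(t) + noise_sd · ε_v(t),   then mean-centred.

Within-region correlations tend to w²/(w²+σ²); with the defaults
w = 0.7, σ = 1 that is ≈ 0.33, comfortably above the r0 = 0.25 edge
threshold.  In group 1 only, w is raised by `effect_size` in the
designated effect regions — a planted, known degree difference.  With
`effect_size = 0` the group label never enters the generative law, so
null cohorts are exact.  MoCA scores are drawn uniformly from [18, 25]
(group 1) and [26, 30] (group 2); only the < 26 rule matters
downstream.  Per-subject randomness comes from
`SeedSequence(master_seed, spawn_key=(subject_index,))`, which is
platform-stable.

Defaults mirror the study design: 51 + 48 subjects, 240 timepoints,
3 mm isotropic voxels.  The default grid is a 16³ desk-scale stand-in
(~1 600 in-mask voxels) for the 61×73×61 whole-brain template; full
scale is a configuration choice, not a test default.  The generator
makes no claim about the spatial covariance of real zDC maps — it
plants known degree differences, nothing more — so passing calibration
tests demonstrates that the pipeline detects (and does not hallucinate)
degree effects, not that it reproduces patient-level effect sizes.

## Calibration experiments

The study's patient-level classification numbers cannot be recomputed
without the undeposited scans, so `neurodc.experiments` validates the
pipeline by properties, at sizes chosen for a single CPU:

* **Planted effect** — 12³ sphere (~550 voxels), 8 regions, 3 effect
  regions, n = 51/48, T = 240.  `effect_size = 0.08` was calibrated
  once so the per-region zDC separation is ≈ 1 pooled SD; pooled-LOOCV
  linear-SVM AUC is then expected ≥ 0.85 in the large majority of
  replicates.
* **Null permutation** — 8³ sphere (~140 voxels), 6 regions, n = 20/20,
  `effect_size = 0`, 99 permutations, selection re-run per permutation
  (5-fold CV over a 23-point penalty grid — a desk-scale rendition of
  the selection protocol; permutation-p validity holds for any fixed
  selection procedure).  p-values are conservative here because
  zero-feature selections tie the statistic at exactly 0.5.
* **Null accuracy** — iid-noise features, n = 15/15, fixed-C linear
  SVM.  The hyperparameter search is fixed deliberately: an
  accuracy-driven inner search on pure noise is itself strongly
  anti-learning under leave-one-out (mean accuracy well below chance)
  and would confound the calibration being measured.  This LOOCV
  pessimism on null data is a known small-sample phenomenon, and one
  reason the dedicated leakage test documents the bias of selecting
  features once on all data before LOOCV.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1]; zero-variance voxels raise an
  error naming the offending grid coordinate.
* Map standardisation uses the population SD and raises on constant
  maps; `fwhm = 0` smoothing is the exact identity.
* Region means raise on regions with no in-mask voxels; feature tables
  reject missing values and unknown labels.
* Pruning raises on constant columns; selection requires both classes
  and at most min-class-count folds.
* Permutation p-values live in [1/(B+1), 1] by the add-one rule.
* Provenance records config, software version and artifact SHA-256
  hashes; wall-clock timestamps are recorded only on request so that
  rerunning a config yields byte-identical artifacts.

## Known limitations

* The generator omits hemodynamics, head motion, physiological noise
  and spatial autocorrelation of real BOLD data.
* The uncorrected KS normality screen is anti-conservative with
  estimated parameters (Lilliefors flag available).
* Published kappa values for this kind of analysis cannot always be
  reconciled with the printed sensitivity/specificity pairs and group
  sizes; the closed-form kappa from a reconstructed confusion is
  reported without forcing agreement.
* The default protocol performs feature selection once on the full
  cohort before LOOCV (as in the source analysis); this leaks label
  information and inflates null AUC, which a dedicated test
  demonstrates.  Nested per-fold selection is available.
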