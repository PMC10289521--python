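# Methods

`srsradiomics` implements a dual-center MRI-radiomics pipeline for
predicting whether a brain metastasis (BM) progresses after stereotactic
radiosurgery (SRS). This note documents the models and procedures, the
parameters that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Progression endpoint

BM size is tracked volumetrically. Where only three perpendicular maximum
diameters are available, their product approximates volume. A BM is labeled
progressed at the first follow-up whose volume exceeds the pretreatment
baseline by at least

```
threshold = max(0.25 * baseline_volume, 27 mm^3)
```

The relative 25% criterion is the classic volumetric rule; the absolute
27 mm^3 floor adapts the RANO-BM 3 mm unidimensional change floor to three
dimensions ((3 mm)^3) so that clinically insignificant absolute changes in
sub-100 mm^3 lesions do not count as progression. The two regimes exchange
at a 108 mm^3 baseline; exactly there the relative rule is reported.
Change is always judged against the original baseline rather than the
nadir, so shrinkage followed by regrowth short of baseline + threshold is
not progression. Pseudo-progression is not computable from size series
alone; a per-lesion flag (set by clinical adjudication upstream) forces a
negative label.

## Image preprocessing and feature extraction

Pretreatment T1w contrast-enhanced volumes are Z-score normalized against
healthy brain — mean and SD taken over the brain mask minus the GTV — and
hard-clipped at ±3 SD, which both removes scanner-dependent intensity
scaling and limits outlier influence. Clipping is interpreted as a hard
clamp; the output stays on the z-scale (no rescaling to a positive range).
Volumes are then resampled to 0.5 mm isotropic voxels (trilinear for the
image, nearest-neighbour for masks, preserving binarity), and the GTV
intensities are discretized into a fixed COUNT of 64 bins over the ROI's
own [min, max] range (a constant ROI maps to bin 1).

The feature schema is the standard 107-name set (18 first-order, 14 shape,
24 GLCM, 16 GLRLM, 14 GLDM, 16 GLSZM, 5 NGTDM). The native extractor
computes the subset the downstream analyses rely on, with IBSI-style
definitions:

* first-order mean, median, range, minimum, maximum, energy (sum of
  squared intensities), skewness and non-excess kurtosis (moment ratios
  m3/m2^1.5 and m4/m2^2) on the ROI intensities, and entropy on the
  64-level histogram;
* mesh-free shape surrogates: voxel-count volume, exposed-face surface
  area, surface-to-volume ratio, sphericity derived from those two, and
  principal-axis lengths (4·sqrt of the coordinate-covariance eigenvalues)
  with elongation and flatness;
* GLCM contrast, joint entropy, inverse difference normalized (normalized
  by the bin count), cluster shade, and informational measure of
  correlation 2 — symmetric co-occurrence matrices at distance 1 for the
  13 unique 3-D directions, features computed per direction and averaged;
* GLSZM zone entropy over 26-connected iso-intensity zones;
* all five NGTDM features over the 26-neighbour average gray-tone
  difference, with single-gray-level conventions: coarseness saturates at
  1e6, contrast/strength are 0, busyness is 0 when its denominator
  vanishes.

Remaining schema names may be merged from an external extractor and are
otherwise NaN with a `computed_mask` recording provenance. Texture
features on a single-voxel ROI are flagged undefined. Direction-averaged
textures are invariant to 90° axis-aligned rotations (verified to 1e-9)
and all post-normalization features are invariant to a constant intensity
shift of the raw scan. Texture values are validated against brute-force
enumeration oracles on small instances; no third-party extractor is used
at run time.

## Univariate statistics

Categorical clinical features use the uncorrected Pearson chi-squared test
(upper tail, df = (r−1)(c−1)); uncorrected Pearson reproduces every
published categorical p-value from the reconstructed per-category counts
at printed precision, which settles the continuity-correction question.
Continuous clinical and radiomic features use the two-sided Wilcoxon
rank-sum test — exact null distribution for small tie-free samples,
tie-corrected normal approximation otherwise. Small expected cell counts
are logged but never block computation, and no multiplicity correction is
applied anywhere. Radiomic results are summarized per feature class as the
count and fraction of features with p < 0.05. In the two-cohort report the
"A vs B" comparison groups rows by dataset membership, not by the
`center_id` column, so degenerate self-comparisons behave as expected.

## ComBat harmonization

Center effects on radiomic features are removed with parametric
empirical-Bayes location/scale (ComBat) adjustment, with no biological
covariates: each feature is standardized by its grand mean and pooled
within-center SD, per-center shift and scale estimates are shrunk toward
center-level normal and inverse-gamma priors (moment-matched; iterative
conditional estimation to a 1e-6 relative tolerance), and the inverse
transform is applied. Omitting covariates is deliberate: harmonization is
applied only to radiomic features, and conditioning on the outcome would
leak labels across train/test splits. Zero-variance features are flagged
and passed through unchanged. The implementation agrees with
Bioconductor's `sva::ComBat` (parametric, no covariates) to ~1e-5 on test
matrices.

By default harmonization for cross-center experiments is fit on the union
of both cohorts' feature matrices before training. This mirrors
harmonization as a site-level preprocessing step but lets test-set feature
distributions influence the correction; the run logs this, and a
train-only fit is available (`combat_fit_on="train"`).

## Forest modeling

`ProgressionForest` is built from a cohort: categorical clinical features
are one-hot encoded (drop-first, category order learned on the training
cohort and reapplied verbatim to test cohorts), and radiomic features pass
through a greedy correlation filter in schema order — a feature is removed
when its |Spearman ρ| with any already-kept feature exceeds 0.8 (Pearson
available by config; constant features are removed with reason
"constant"). The greedy order makes the kept set deterministic and
independent of sample order.

`fit(seed)` grid-searches forest hyperparameters — trees ∈ {100, 300, 500},
features per split ∈ {√p, p/3, p}, minimum leaf ∈ {1, 3, 5} — maximizing
out-of-bag (OOB) AUC with class-balanced sample weights, then refits the
winner. Tree counts are explored by warm-started growth so each
(max_features, leaf) cell is built once. The grid is an artifact decision:
the published methodology defers its search space to an unavailable
supplement, so a small, fully configurable grid is used. With scikit-learn
≥ 1.7 the per-tree bootstrap draw is weighted by the sample weights; the
package's OOB bookkeeping (and its OOB permutation importance) mirrors
that draw exactly.

Scores are forest vote fractions; thresholds compare with ≥. The ROC is a
threshold sweep over unique scores (ties share a point), trapezoidal AUC,
endpoints (0,0) and (1,1). The operating point is the upper-left point
minimizing FNR² + FPR², ties toward lower FPR, chosen on the TRAINING OOB
ROC and transferred to test scores — the test set never influences the
threshold. Test metrics are MCR, FNR, FPR at that threshold plus the
threshold-free AUC.

Raw feature importance defaults to Breiman-style OOB permutation
importance (mean increase in a tree's OOB misclassification rate when one
feature is permuted among its OOB samples); impurity importance is
available by config.

## Validation designs

* **Model-external**: train one locked model on one center, test on the
  other, operating point transferred from the training OOB ROC. Optional
  ComBat and/or restriction to a consolidated feature subset.
* **Methodology-external**: the training procedure (filter →
  hyperparameter search → train → OOB operating point) is locked and rerun
  under bootstrap resampling, 250 repetitions by default. Resampling is at
  PATIENT level: patients are drawn with replacement to the original
  patient count, the training multiset is their BMs (with multiplicity)
  and the test set is the never-sampled patients' BMs, so BMs of one
  patient never straddle the split. BM-level resampling is available for
  fidelity experiments. A split whose train or test side is single-class
  is redrawn with an incremented seed (logged, max 20 retries).
* **Pooled**: both cohorts are pooled before the same bootstrap, with
  per-center metrics computed on each repetition's test subset (a
  repetition missing a center, or single-class within it, contributes no
  row for that center and is logged).

Aggregation: mean ROC by vertical averaging of per-repetition test ROCs on
a fixed 101-point FPR grid, with a 95% band for the mean curve; mean
metrics with normal-approximation CIs (mean ± 1.96·SD/√n_reps; percentile
CIs by config). The apparent AUC for the 0.632+ correction is the
resubstitution AUC of a model trained on the full dataset. The correction
is

```
R = clip((apparent − boot) / (apparent − 0.5), 0, 1)   (0 if denom ≤ 0)
w = 0.632 / (1 − 0.368·R)
AUC_0.632+ = (1 − w)·apparent + w·boot
```

Note a calibration caveat found while validating the pipeline: under null
(permuted) labels the repetition-wise CI of the mean AUC under-covers 0.5
(≈40% coverage rather than 95%). All repetitions of one run share a single
fixed labeling, and forest scores are strongly correlated across
repetitions, so the mean AUC carries a labeling-level variance component
(SD ≈ 0.06 for ~117 BMs at ~17% prevalence) that the rep-to-rep CI cannot
see. The CI is a precision statement about the resampling mean, not a
confidence interval for the population AUC; the package keeps the normal
CI as the default (it matches the magnitude of published bootstrap CIs)
and documents this limit rather than widening the interval.

## Importance consolidation

Per repetition, raw importances over the used features are min-max
normalized to [0, 1]; features removed by the correlation filter score 0.
Per-feature scores are averaged across repetitions and re-normalized by
the maximum so the top feature scores 1 (division by the maximum, not a
second min-max, so an all-equal average maps to all-1 and the pipeline is
idempotent on processed profiles, whose minimum is pinned at 0 by the
filtered features). Features scoring ≥ 0.75 are "highly important". The
cross-center consolidated ranking scores each feature by the MINIMUM of
its per-center scores (a feature must matter at both centers), sorted
descending with lexicographic tie-breaks, top 10 by default. The
consolidation sweep reruns model-external validation (ComBat applied,
radiomic only) restricted to the top n consolidated features, n = 1..10,
in both transfer directions, and reports the n maximizing the mean
cross-direction AUC.

## Synthetic two-center cohorts

The generator emulates the statistical structure of a dual-center SRS
study so the full pipeline is testable without protected data. Defaults
(all configurable):

| parameter | default | meaning |
|---|---|---|
| n BMs / patients | (123, 117) / (99, 62) | cohort sizes per center |
| prevalence | (0.220, 0.171) | progression fraction per center |
| radiomic features | 107 | canonical schema names |
| signal features | zone entropy, inverse difference normalized, cluster shade, IMC2 | carriers of the true outcome signal |
| signal effect | 1.0 log-odds per SD | per-feature latent effect |
| volume effect | 0.6 log-odds per SD of log-volume | the one shared clinical predictor |
| batch shift SD | 0.75 (units of feature SD) | additive center effect per feature |
| batch scale range | (0.7, 1.4) | multiplicative center effect per feature |
| block correlation | 0.5 over 10 blocks | within-block feature correlation |

Radiomic vectors come from a latent block-correlated Gaussian (contiguous
feature blocks, equicorrelated within block). Labels are drawn from a
logistic model on the latent (pre-batch) signal features plus standardized
log-volume, with a per-center intercept solved numerically so the expected
prevalence matches the configuration. Batch effects are applied afterwards
to radiomic features only, in exactly the location/scale form ComBat
assumes (x = α + γ_c + δ_c·ε), so harmonization can in principle undo
them. Clinical categorical features are drawn from per-center multinomials
approximating the published cohort marginals (e.g. systemic therapy 92% vs
49%, single-fraction 92% vs 50%); volumes are log-normal with medians
≈3500 vs ≈329 mm³ and log-SD 1.0 (chosen to match the published ranges);
ages are truncated normal around 59 vs 67 years. Patients cluster BMs via
a truncated geometric repaired to the exact BM total. Within-patient
outcomes are independent given features (the within-patient correlation is
not identifiable from the published material; independence is the default
and the clustering still matters through patient-level resampling).

The default batch regime was calibrated once so that roughly 80% of
radiomic features differ significantly between centers — the regime a
dual-center study actually observes (78.6% published) — and then frozen.

What the generator does NOT emulate: real texture values or their physical
constraints (features are exchangeable Gaussians, not functions of an
image), scanner-model substructure within a center, within-patient outcome
correlation, informative follow-up scheduling, or center-specific
biological effects (a non-signal feature has the same null relation to
outcome at both centers). Consequences: passing tests demonstrate the
machinery — labeling, harmonization, leakage-free validation, importance
consolidation — under a known generative law; they do not certify
real-data accuracy levels. One visible consequence: in the consolidation
sweep the cross-direction AUC is flat beyond the true support size rather
than peaked, because no mechanism makes extra features actively harmful
across centers; the sweep's optimum therefore concentrates on the planted
support only in the sparse, strong-signal recovery regime
(block_correlation 0, effect 1.5), which is what the recovery tests use.
Under the defaults (block correlation 0.5) the block-mates of signal
features legitimately carry signal and the optimum sits slightly above the
planted count.

## Numerical and determinism choices

* One top-level seed expands into per-stage and per-repetition seeds via
  `numpy` SeedSequence; fixed seed ⇒ byte-identical cohorts and identical
  experiment JSON.
* Hyperparameter ties break toward the earlier grid cell (deterministic
  iteration order); consolidation ties break lexicographically; operating
  point ties break toward lower FPR.
* Degenerate inputs: σ = 0 normalization region, empty ROI, single-class
  labels, single-center ComBat and unseen centers raise immediately with
  named errors; zero-variance features and all-zero importance repetitions
  are flagged and logged, never silently dropped.
* Test-suite and acceptance-script experiment sizes are scaled for
  desk-scale runs: single-cell hyperparameter grid (100 trees, √p, leaf 3)
  and 20–50 bootstrap repetitions; the library defaults remain the full
  grid and 250 repetitions. A full-grid 250-repetition methodology run on
  one CPU takes on the order of an hour.

## Known limitations

* The pooled-fit ComBat default leaks test-feature distributions (not
  labels) into preprocessing; use `combat_fit_on="train"` for strict
  separation.
* The normal-approximation CI of bootstrap means under-covers
  dataset-level uncertainty (see above).
* The native feature set covers the analyses' needs but not all 107 names;
  GLRLM/GLDM families and mesh-based shape descriptors must come from an
  external extractor if required.
* Real-data headline accuracies are not reproducible here: the two
  institutional cohorts are not deposited, so all quantitative checks run
  on synthetic analogues.
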