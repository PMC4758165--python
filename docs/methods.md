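# Methods

This note records the statistical model behind the package, the
defaults that matter, what the synthetic cohorts do and do not emulate,
and the numerical/design choices made where more than one reasonable
option existed.

## Model and procedure

The object under validation is a *biomarker-panel × classifier
combination*. Two panels are compared: the base panel (age, sex, APOE
ε4 carriage, CSF Aβ42, t-Tau, p-Tau181; "Experiment 1") and the
extended panel adding z-scored log C3 and factor H ("Experiment 2").
Stage labels are binary: 0 = MCI-AD (MCI with CSF t-Tau/Aβ42 ≥ 0.39,
boundary inclusive), 1 = mild AD dementia.

Performance is the Gini index G = 2·AUROC − 1 (Somers' D of the
continuous score against the stage label, ties half-weighted). This
definition makes "chance" literally G = 0 and admits negative values
for worse-than-chance ranking; the empirical p-value of a Gini
distribution is the fraction of values **at or below 0**. Counting
G ≤ 0 rather than G = 0 alone treats below-chance performance as
chance-equivalent, which is the conservative reading when negative
values are logically possible but uninformative.

Stage 1 draws `n_folds` (default 1000) independent random partitions of
the training cohort into 180 training and 50 internal-CV subjects.
Partitions are class-stratified by default (largest-remainder integer
allocation), which preserves the MCI-AD:AD ratio in every fold to
rounding and makes single-class CV sets impossible; an unstratified
mode exists, and there single-class CV folds are dropped from both
numerator and denominator of the p-value with a logged count rather
than imputed. Every algorithm and both experiments are evaluated on
the *same* partitions so that fold-to-fold variation never differs
between combinations.

Stage 3 selects combinations with p strictly below α = 0.05 with no
multiplicity adjustment — the selection is deliberately liberal because
each selected combination must still survive independent-cohort
validation; a stricter, adjusted threshold can be applied to the final
Stage-4 p-value via configuration.

Stage 4 refits each selected combination **once** on the full training
cohort and transfers that single frozen model — learner plus its
internal standardization — to the test cohort. (Which fitted object
should transfer is genuinely open: candidates are the 1000 fold
models, a best fold, or a full-data refit. The refit is the canonical
choice here: it uses all training information, is deterministic given
the seed, and keeps the frozen artifact unambiguous. An ensemble
reading of the per-subject probability is possible but not
implemented.) Validation draws `n_boot` (default 1000) balanced
bootstrap test sets of `per_class` (default 50) MCI-AD and AD subjects
**with replacement** — replacement is forced because a real test cohort
can have fewer subjects in a class than the replicate size (e.g. 22 AD
for 50 slots). Sensitivity is the fraction of AD subjects labeled AD,
specificity the fraction of MCI-AD labeled MCI-AD, each averaged over
replicates. A replicate whose scores are all tied has AUROC ½, hence
G = 0, and counts into the p-value mass.

P(AD) for a test subject is (times labeled AD) / (times sampled) over
the Stage-4 bootstrap of the selected model; subjects never sampled
have undefined P(AD) and are flagged and excluded from strata. The
stratum boundary is inclusive on the dementia side: P(AD) = 0.5 is
"likely mild dementia". Longitudinal contrasts reduce each subject to
one summary per cognitive domain — the mean Z (LEVEL, a severity
contrast) or the least-squares slope in Z/month (SLOPE, a progression
contrast; subjects with fewer than two scored visits are excluded with
a log entry) — and compare strata with an unequal-variance (Welch)
two-sample t test and two-sided 95 % CI. Estimates are oriented
likely-MCI minus likely-dementia, so positive values mean the low-P(AD)
stratum is less impaired or declines more slowly. A mixed-effects
longitudinal model would use the visit-level data more efficiently but
is out of scope; the two-step summary-then-Welch procedure is the
simplest one that yields the target quantities (a Z difference and a
Z/month difference, each with CI), and its p-values are exactly
calibrated under permutation of stratum labels (verified by a
Kolmogorov–Smirnov uniformity test in the suite).

## Classifier registry

All nine learners run behind one contract: `fit` (deterministic given
data and seed), `predict_score` (continuous, higher = more AD-like) and
`predict` (hard labels; a score exactly at the decision threshold maps
to AD — the tie must break somewhere, and breaking it toward the
positive class keeps `predict` consistent with the inclusive P(AD)
boundary). Scores are class probabilities where the learner provides
them and signed distances to the decision boundary for the perceptron
and SVM; only the ranking matters for the Gini, and rankings are what
these choices preserve.

No hyperparameter search is performed anywhere. The reference
configuration is fixed and versioned with the package (overridable per
run): RBF-kernel SVM (C = 1, scale gamma) — a non-linear kernel is the
point of using an SVM on interacting biomarkers; random forest with
500 trees; AdaBoost on depth-1 stumps and gradient boosting, 100
stages each; k = 5 nearest neighbors; logistic regression and
perceptron with generous iteration caps; Gaussian naive Bayes; CART
decision tree. Scale-sensitive learners (logistic, perceptron, KNN,
SVM) standardize features internally using **training statistics
only**, stored in the frozen model — this both prevents CV leakage and
makes the frozen model self-contained when it crosses cohorts. A
reduced configuration (`REDUCED_HYPERPARAMETERS`: 50 trees, 25 boosting
stages) exists for multi-replicate calibration studies, where tens of
thousands of fits are needed and the property under test — null
calibration of the empirical p-value — holds for any fitted classifier
regardless of ensemble size.

Per-fold fit seeds derive deterministically from (master seed, fold
index, algorithm index) via `numpy.random.SeedSequence`, so any fold of
any run can be reproduced in isolation.

## C3 harmonization

C3 is right-skewed and platform-dependent, so each subject's C3 enters
the model as z(ln C3) computed against the **same cohort's** cognitively
normal reference: z = (ln c3 − mean_ref) / sd_ref with the sample SD
(n−1). Natural log is used; the base is immaterial because it cancels
in the z-score. Normalization is strictly per-cohort — pooling
references across cohorts would re-import the assay shift the z-score
exists to remove. A multiplicative cohort-level assay factor is
additive in log space and vanishes exactly under this transform; the
synthetic-data suite verifies the vanishing empirically. FH is
approximately normal and enters untransformed. References with fewer
than two subjects or zero spread are hard errors, not warnings.

## Synthetic cohorts

`xmittn.simulate` draws cohorts from published-style group summaries:
per-group truncated-normal (at zero) analyte distributions, Bernoulli
sex/APOE mixes, and group sizes 135/95/115 (training: MCI-AD/AD/normal)
and 51/22/25 (test). The training:test C3 assay factors are 1.0 and
0.6. Log-C3 group distributions are parametrized by their z-scores
relative to the normal reference (location ln 150 000, scale 0.45 in
ln pg/mL — the raw scale is arbitrary for the pipeline and chosen only
to resemble plausible assay output). Cross-feature structure is
limited to two linear age gradients: +0.015 ln-units/year on log C3
(all groups) and +12 pg/mL/year on FH confined to the biomarker-
positive groups (a diagnosis × age interaction; age leaves FH flat
when CSF biomarkers are normal). These coefficients are package
choices of realistic magnitude, not estimates from any published fit.
The stated group (mean, SD) are the **marginal** moments: the
age-gradient share of variance is carved out of the stated SD, so
generated group moments match their specification directly.

Every MCI-AD subject is redrawn until t-Tau/Aβ42 ≥ 0.39 (capped
rejection sampling), so the inclusion rule holds by construction. This
truncation necessarily biases the realized MCI-AD t-Tau mean upward
relative to the untruncated specification (≈ +14 pg/mL at the default
parameters, ≈ 2.8 standard errors at n = 135); the moment-recovery
test therefore checks the constrained pair against an independent
rejection-sampling oracle rather than the raw specification. This is a
property of the inclusion rule, not a generator defect.

Scenario constructors define the study conditions for the calibration
suites. `generate_null_pair` makes the AD group distributionally
identical to MCI-AD within each cohort **including the ratio
constraint** — without constraining both classes, the truncation itself
is class signal and a linear model finds it (this was caught by the
null-calibration suite during development). `generate_staged_pair`
starts from the null configuration and shifts only the AD group's
log-C3 and FH means by a stated number of group SDs (default −1.0:
lower complement in the more advanced stage), optionally steepening AD
cognitive slopes; at zero shifts it reduces exactly to the null pair.

Longitudinal visits run at 0/6/12/18/24 months (a reduced span of
typical 6–12-monthly follow-up), with per-subject random intercepts
(SD 0.5 Z), random slopes (SD 0.01 Z/month) and visit noise (SD 0.3 Z).

What the generator does **not** emulate: within-group correlations
among analytes beyond the two age gradients (no published covariance
structure to target — a correlation hook could be added to the cohort
recipe), plate-level assay effects beyond the single cohort factor,
missing data, dropout, non-linear trajectories, and diagnostic
mislabeling. Passing calibration/power suites on these cohorts
therefore shows the *pipeline's* statistical properties (null
calibration, leakage-freedom, signal recovery, harmonization), not that
real cohorts would yield any particular result.

## Problem sizes in the test and acceptance runs

The suite runs the null calibration at 20 replicate cohort pairs × 100
folds × all nine algorithms × both experiments (reduced ensemble
configuration), the signal-recovery study at 20 replicates × 200 folds
(SVM only, reference configuration), bootstrap checks at 200–1500
replicates, and slope recovery at 100 replicates of 22 + 22 subjects.
`scripts/acceptance.py` uses 5 null replicates and 10 signal
replicates at the same fold counts. These sizes are the package's
declared study conditions for its own verification.

On slope recovery: the per-replicate Welch CI has ~95 % true coverage
of the 0.035 Z/month gap (measured 95.5 % over 2000 Monte-Carlo
replicates of the exact pipeline), so the suite's acceptance event is
that the *estimate* lands in the reported 95 % band for that contrast
(0.011–0.059 Z/month) and that the replicate-mean estimate is unbiased;
raw truth-in-CI coverage in any single 100-replicate run fluctuates
binomially around its nominal level, as it should.

## Numerical choices and degenerate inputs

- Gini via `sklearn.metrics.roc_auc_score` (trapezoidal/Mann–Whitney;
  verified against exhaustive pair counting to 1e-12); single-class
  label vectors are an error, never a default value.
- All-tied score vectors: AUROC ½, Gini 0 (counts as chance).
- Stage-3 p-values use only finite Gini values; an all-missing
  distribution is an error.
- Largest-remainder fold allocation caps per-class draws at class size
  and redistributes overflow; infeasible plans (train + CV > cohort)
  are configuration errors.
- Empty diagnosis groups summarize as n = 0 with null statistics;
  single-subject groups report null SDs (n−1 denominator throughout).
- Percentages are always 100 × count / group n.
- Rejection sampling is capped (default 10 000 draws/subject); an
  infeasible constraint raises rather than looping.
- Seeds everywhere are derived via `SeedSequence` tuples and kept below
  2^31.

## Known limitations

- The nine-learner reference configuration is a declared convention;
  results for ensemble learners depend on it, and no claim is made that
  it is optimal for any particular cohort.
- Stage-4 transfers a single full-data refit; an ensemble-of-fold-models
  variant could yield different P(AD) granularity.
- The two-step longitudinal contrast ignores within-subject visit
  correlation structure beyond the per-subject summary; CIs are valid
  for the summary-level contrast, not for a visit-level mixed model.
- Synthetic cohorts are moment-matched, not joint-distribution-matched,
  to real data; power estimates on them do not transfer quantitatively
  to real cohorts.
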