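# Methods

This note documents the models, algorithms and design choices behind
`shockpanel`, in the order the pipeline runs them.

## Synthetic cohort model

The generator (`cohortsim`) emulates the statistical structure of a
single-center emergency-department metabolomics study so that the whole
analysis chain can be exercised with known ground truth.

**Cohort.** Four severity subgroups — noninfectious control (28),
nonseptic infection (34), nonshock sepsis (32), septic shock (32) — give
126 study patients by default; the class label pools the first three as
*nonshock*. (The clinical-characteristics variant with 92 nonshock
patients is available by setting `n_infection=32`; the two enrollment
totals circulating for this design differ by two patients and we expose
the choice rather than resolve it.) One procedural blank and a pooled QC
after every 10 study injections complete the run; injection order is
randomized once per simulation.

**Intensities.** Feature intensities are lognormal: per-feature log₁₀
location ~ N(5.5, 0.6²) across features, within-feature biological SD
0.35 (log₁₀). These place typical peak areas around 10⁵–10⁷ with the
spread seen in serum profiling. Per-feature S/N values are lognormal with
median ≈ 50, so a few percent of features legitimately fail the S/N > 10
extraction rule.

**Planted markers.** Exactly `n_markers` (22) features carry a
class-dependent shift on the log scale, `n_markers_up` (9) upward in
shock and the rest downward. Severity subgroups receive graded fractions
0, ⅓, ⅔, 1 of the shift, so severity trends exist by construction. Three
realism features shape the signal:

- *Per-patient response*: each patient expresses the shift to a
  patient-specific degree r ~ Beta(mean 0.75, SD 0.25). This is what makes
  some septic-shock patients metabolically borderline — without it, 22
  features at Cohen's d = 1.5 would separate the classes perfectly and no
  panel larger than a handful of features would ever be needed.
- *Pathway axes*: the response factors are drawn independently on 6 axes
  and markers load on the axes round-robin, reflecting that a panel spans
  several metabolic pathways rather than a single latent severity score.
  The number of axes controls marker redundancy: one axis makes all
  markers interchangeable, one axis per marker makes them fully
  independent.
- *Effect heterogeneity*: per-marker effect multipliers are lognormal with
  mean 1 and CV 0.25, so some markers are strong and some marginal.

The raw log shift δ is solved numerically (Brent) so that the **marginal
shock-vs-pooled-nonshock Cohen's d equals `marker_effect`** after
accounting for the variance the severity gradient and the response factor
add to the pooled classes; `marker_effect` is therefore a calibrated,
interpretable knob (default 1.5, which puts univariate marker AUROC near
0.86). Marker features get an S/N floor of 15 and an abundance floor near
the filter thresholds, encoding that panel metabolites are by construction
confidently detected compounds.

**Drift, missingness, blank.** A smooth multiplicative drift
(1 + amplitude·(t + 0.1·sin 2πt), t = scaled injection order) is applied
to every injection; QC replicates have technical SD 0.05 (log₁₀).
Intensities below the per-feature `missing_rate` quantile (default 2 %)
are left-censored to missing. The blank carries ~300-fold lower background
for most features, plus a 2 % subset of designated background features at
study-level intensity that blank subtraction should remove.

**Survival and clinical covariates.** 28-day death is Bernoulli with
probability logistic in the standardized planted-marker score; the
intercept is solved per class so the expected mortality matches the
configured rates (37.5 % shock, 22.8 % nonshock). Admission covariates
(CRP, PCT, lactate, WBC) are lognormal around the published group means,
deliberately only weakly informative.

**Targeted re-measurement.** `simulate_targeted_remeasurement` subsamples
a 62-patient cohort (32 shock / 30 nonshock by default), restricts to the
panel, and multiplies each intensity by a mean-one lognormal error with
the requested CV (σ² = ln(1+CV²)), emulating a second platform. The
pipeline additionally injects per-sample loading variation plus a spiked
internal standard and removes both with internal-standard normalization,
exercising the semiquantitative MRM pattern.

**What the generator does not emulate.** Raw spectra, adducts/isotopes,
peak-picking artifacts, retention-time warping, batch effects beyond
smooth drift, correlated blocks among *non-marker* features, and missing
clinical covariates. Tests passing on this generator show the pipeline's
algebra and its selection/validation logic are sound and calibrated — not
that real cohorts meet the generator's assumptions.

## Preprocessing

All threshold comparisons are strict, matching the stated extraction
rules: max study intensity > 100 000, S/N > 10, |Δm/z|/mz < 5 ppm,
|Δrt| < 0.5 min. Blank subtraction removes a feature when its mean study
intensity ≤ 3× its mean blank intensity (`blank_fold`, configurable);
removal rather than subtraction was chosen because background ions are
artifacts, not offsets. Coeluting features are grouped by single linkage
and each group is represented by the per-sample maximum intensity with
intensity-weighted mean m/z and RT; the maximum (not the sum) keeps the
representative on the original intensity scale.

QC drift correction follows the QC-RLSC pattern: per feature, a LOWESS
curve (frac = 2/3, zero robustness iterations) through QC intensity vs
injection order — linear interpolation when fewer than 5 QCs — evaluated
at every injection (clamped at the run edges), divided out, and rescaled
to the QC median. A feature is left untouched whenever correction would
increase its QC relative SD, making the step non-degrading by
construction. Fewer than 3 QCs is an error instructing the caller to skip
normalization explicitly.

The model-matrix transform (floor-imputation at half the minimum positive
training intensity, log₁₀, per-feature centering/scaling with training
statistics) is fit on training samples only and refit inside every
cross-validation fold, so no statistic of a held-out sample leaks into its
own prediction. Zero-variance training features are dropped and recorded.

## Panel selection

**Step 1 — stability selection.** 20 iterations; each draws a
class-stratified ⌈0.9·n⌉ subsample (largest-remainder allocation) and fits
a sparse binomial model; a feature "receives weight" when |β| > 10⁻⁸, and
features weighted in ≥ `min_count` = 10 iterations become candidates. The
sparse family is the **elastic net** (l1_ratio 0.5, fit by SGD on the
logistic loss with exact zeros): a pure L1 penalty stops adding features
once ~10 correlated markers already separate the training set, which
silently caps the frequency rule's recall; the elastic net's grouping
effect keeps correlated markers in together. The penalty strength is
calibrated once per selection run so one fit assigns weight to roughly
`per_iter_nonzero` = 100 features (count-controlled stability selection in
the Meinshausen–Bühlmann style) — strength chosen by internal CV is
unstable under p ≫ n separability and collapses to over-sparse fits.

**Step 2 — backward elimination.** From the candidates, repeatedly refit
a ridge-penalized model (C = 0.05) on standardized inputs, drop the
feature with the smallest |β| (ties: lexicographic by feature id), and
record the leave-one-out accuracy of the reduced subset; the panel is the
visited subset with the best metric, ties resolved toward the smaller
subset. The strong ridge is a deliberate choice: with weak shrinkage the
train-set LOOCV saturates at exactly 1.0 across a wide range of subset
sizes and the tie rule collapses the panel to a handful of features;
C = 0.05 keeps the metric-vs-size trace peaked, which is also the shape
such traces show on real cohorts. AUROC is available as the elimination
metric via `elimination_metric="auroc"`.

**Known limitation (measured).** With 2892 features and 86 training
samples, stability selection necessarily admits a few dozen features that
correlate with the training labels by chance; the train-set LOOCV used
during elimination cannot demote them relative to mutually redundant true
markers. Candidate-stage recall of planted markers is ≈ 0.97 under the
default generator, but final-panel recall averages ≈ 0.47 (10 seeds,
marker effect 1.5) — roughly the candidate purity times the panel size.
This is a property of in-sample wrapper selection at this n/p, not of a
particular penalty; it is why the held-out test set, never touched before
the final evaluation, is the only performance number to trust.

## Classifier and evaluation

The classifier is penalized logistic regression. The final model uses the
elastic net with strength chosen by 3-fold internal CV (log-loss) on the
training set; LOOCV and elimination refits use ridge with fixed strength
for speed and stability. Unpenalized fits detect perfect separation
(training log-loss < 10⁻⁴ with diverging coefficients) and raise an error
suggesting a penalty. Class calls threshold the predicted probability at
0.5; the study cut-off is unpublished and 0.5 is the neutral default.

The 70/30 split is stratified with per-class floor rounding, which on
32 + 92 patients reproduces 86 train / 38 test with 10 shock test
patients. LOOCV refits the transform and model on every fold and assembles
one report from the n held-out scores; note LOOCV accuracy on data whose
features were selected using the same training set is optimistically
biased (both resubstitution and LOOCV training numbers are reported and
labelled). AUROC uses midranks (ties count ½) and is exactly the
trapezoidal area under the empirical ROC; this equivalence is asserted to
10⁻¹² in the tests.

## Cohort statistics

Group comparisons use pooled-variance Student's t by default (Welch by
flag), matching the clinical-table convention; proportions use Pearson's
chi-square without continuity correction. Per-metabolite univariate AUCs
are orientation-corrected (max(AUC, 1−AUC) with a direction flag).
Severity/survival contrasts run all six subgroup pairs plus dead-vs-alive
per panel feature with star coding at 0.05/0.01/0.001/0.0001; no
multiple-testing correction by default (the presentation convention this
mirrors reports raw t-tests), Benjamini–Hochberg by flag.

## Numerical choices and degenerate inputs

- Seeds: simulation, splitting and selection take independent seeds; all
  randomness flows through `numpy.random.default_rng`. Reruns are
  byte-identical (asserted on output manifests).
- Zero pooled variance in a t-test: t = 0, p = 1 when means agree, error
  otherwise. Constant features: AUC 0.5 flagged "constant"; dropped from
  model matrices.
- Empty candidate set (e.g. null data): the pipeline falls back to an
  intercept-only model, whose tied scores give AUROC 0.5 by convention.
- Problem sizes in the test suite: null-calibration pipelines run at 200
  features (the null property is dimension-free); planted-marker recovery
  runs at the full default geometry (2892 features, ~30 s per seed).
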