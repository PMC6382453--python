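# Methods

This note documents the models and procedures implemented in `ogttbench`,
the defaults they ship with, and what the synthetic cohorts do and do not
establish about behaviour on real data.

## The classifier and its cross-validation protocol

Each candidate model is a ridge-penalized least-squares classifier on the
±1-coded progression outcome. With feature matrix X (n × d) and target y,
the weights minimize ‖y − Xw‖² + λ‖w‖², the intercept is left unpenalized
(features and targets are centered before solving), and the solution is
closed-form through the SVD of the centered, standardized training matrix:
w(λ) = V · diag(sᵢ/(sᵢ² + λ)) · Uᵀy. Because U, s, V do not depend on λ, one
factorization serves the whole penalty grid, which is what makes scoring a
grid of hundreds of models with 100 repetitions practical on a single CPU.
Scores enter the analysis only through their ranking, so the outcome coding
is immaterial to every ROC quantity downstream.

Out-of-sample scores come from repeated nested cross-validation:

* **Outer loop** — stratified k-fold (default 10) holds each participant out
  exactly once per repetition.
* **Inner loop** — within each outer training set, stratified k-fold
  (default 10) evaluates every λ in the grid; the λ with the highest mean
  out-of-fold AUC wins, ties going to the larger penalty. AUC rather than
  squared error is the inner criterion because ranking performance is the
  quantity being optimized end to end; this is a package choice and is
  recorded in the run manifest.
* **Repetitions** — the whole outer/inner procedure is repeated with
  re-randomized folds (default 100) and each participant's out-of-fold
  scores are averaged. Per-repetition fold seeds derive from the master seed
  by a counter, so a run is exactly reproducible while repetitions differ.

Standardization (mean/SD) is always estimated on the training portion of a
split and applied to its held-out portion; the no-leakage property test
(adding a pure-noise feature on a null cohort does not lift AUC) guards the
implementation against standardize-before-split regressions. Inner folds are
reduced automatically when the minority class is too small to stratify;
outer folds require at least one minority member per fold and error
otherwise.

Defaults: `repetitions=100`, `outer_folds=10`, `inner_folds=10`,
`lambda_grid=2^(−10…10)` (21 values). The fold counts are standard practice
for cohorts of a few hundred participants with ~25% events; the λ grid spans
clearly under- to clearly over-regularized fits on standardized features.

## ROC inference

AUC is the Mann–Whitney statistic with ties counted ½, computed from
midranks; it equals the trapezoidal area under the empirical ROC (tested on
random instances). The operating threshold is the F-index cutoff: the point
on the ROC curve maximizing the harmonic mean of sensitivity and
specificity, with the harmonic mean defined as 0 at degenerate points and
ties resolved toward higher sensitivity (configurable in principle; the
tie-break is logged through the manifest). Accuracy, sensitivity,
specificity, PPV and NPV are computed from the 2×2 table induced at that
threshold; an undefined predictive value (empty denominator) is reported as
missing rather than zero.

Variance of the AUC and the covariance between two models' AUCs use DeLong's
structural components: V10ᵢ is the fraction of negatives outranked by
positive i (ties ½), V01ⱼ the mirror over positives; var(AUC) =
var(V10)/m + var(V01)/n with ddof = 1. The implementation is the midrank
O(n log n) form and is verified against a literal O(n²) component
computation over hundreds of random instances. Two CI methods are provided
because practice conflates them: the analytic normal interval
AUC ± z·SE (default), and a class-stratified bootstrap percentile interval
(default 2000 replicates, seeded) that resamples positives and negatives
separately. On well-behaved cohorts the two agree to ~0.02.

The paired comparison of a candidate against the reference model uses
z = ΔAUC / √(var_A + var_B − 2 cov_AB) with a two-sided normal p. When the
variance of the difference is zero — identical score rankings — the result
is flagged degenerate and p = 1 by convention. Type-I error of the test is
checked by simulation (two independent noise models on shared labels):
empirical rejection at α = 0.05 stays within 0.05 ± 0.015 over 2000 draws.

## Multiple testing

The batch of all non-reference comparison p-values is converted to
positive-FDR q-values: q₍ᵢ₎ = min over t ≥ p₍ᵢ₎ of π̂₀·m·t/#{p ≤ t},
evaluated by the step-up minimization over observed p-values and enforced
monotone. π̂₀ is Storey's fixed-λ estimator at λ = 0.5, clipped to at most 1
and floored at 1/m so that a batch with no p above λ does not collapse every
q to zero; setting `pi0_mode="bh"` forces π̂₀ = 1, which reproduces
Benjamini–Hochberg adjusted p-values exactly (cross-checked against
statsmodels in the tests). The significance call follows the two-decimal
convention: q is rounded half-even to two decimals and compared strictly
against 0.05, so q = 0.049 is *not* significant while q = 0.044 is. The
rounding mode is the package's choice; only the rounding rule itself is
externally specified.

Stratified reruns (baseline IFG/IGT vs IFG/IGT-free) report raw DeLong
p-values without a within-stratum q batch, matching how subgroup analyses
of this kind are reported.

## Pairing models with different complete-case sets

Complete-case exclusion is per model: a participant missing any variable of
a candidate set is dropped for that model only. Metabolite columns are
exempt because they are minimum-imputed first (a missing metabolite
abundance typically means below detection limit); all other variables are
complete-case. When a candidate's complete-case subset differs from the
reference model's, the DeLong pairing would be invalid, so the reference is
re-scored by the full nested-CV protocol on the intersection of the two
subsets (cached per subset, noted in the manifest). The candidate's scores
are restricted to the same intersection.

## The synthetic cohort generator

The generator emulates the structure of a prospective nondiabetic OGTT
cohort of 543 participants with 146 progressors: 19 markers (4 clinical,
4 glucose, 4 insulin, HbA1c, 6 metabolites), WHO baseline strata, and
realistic inter-marker correlation.

**Construction.** A latent Gaussian vector with within-class covariance C
and class-conditional mean shifts ±δ (progressors up by (1−p)δ, controls
down by pδ, p the progressor fraction) is drawn per participant. Because the
pooled covariance of such a mixture is C + p(1−p)δδᵀ, the generator solves
for C from the *pooled* correlation target R:
Cᵢⱼ = Rᵢⱼ·√((1+cᵢ)(1+cⱼ)) − p(1−p)δᵢδⱼ with cᵢ = p(1−p)δᵢ², which keeps a
unit diagonal and makes the empirical cohort-level correlations match R
(within ±0.03 at n = 20 000 in the recovery tests) despite the group
separations. If the subtraction leaves C indefinite it is repaired by
eigenvalue clipping and the repair is recorded on the cohort's notes, as is
a repair of a user-supplied indefinite R.

**Effects.** δ is the standardized within-class separation, so a marker's
theoretical single-marker AUC is Φ(δ/√2) (equal-variance binormal);
`calibrate_effect` inverts this. Default δs are calibrated to published
single-marker AUC levels where such levels exist — FPG 0.63, 30-min PG 0.71,
1-h PG 0.75, 2-h PG 0.68, HbA1c 0.67, mannose 0.70 — and to plausible
sub-reference values for markers whose single AUCs are not published
(other metabolites 0.57–0.66, with bradykinin-hydroxyproline negative;
insulin time points 0.60–0.62; clinical factors such that the four-variable
block performs near 0.66). These defaults are the package's study
conditions, not tuning knobs.

**Correlation targets.** Metabolite–glucose and metabolite–HbA1c entries are
published cohort correlations (mannose 0.30/0.32/0.26/0.14 against the four
glucose time points; AHB 0.08 fasting rising to 0.37 at 1 h;
bradykinin-hydroxyproline −0.25 at 1 h; X-12063 0.35 at 2 h; HbA1c–mannose
and HbA1c–X-12063 both 0.16). The OGTT glucose and insulin blocks use the
stylized fact that adjacent time points correlate more strongly than distant
ones (0.4–0.7). Insulin–glucose, metabolite–metabolite and BMI–insulin
entries are stated assumptions — no cohort values exist for them — and sex
and family history are uncorrelated with everything by default.

**Marginals.** Glucose, insulin, HbA1c, age and BMI are affine maps of the
latent scale to measurement units, truncated at zero (fasting glucose
5.7 ± 0.6 mmol/L, 2-h glucose 6.5 ± 1.65 mmol/L, chosen once so the WHO
strata land near the emulated cohort's 86/543 IFG and 112/543 IGT; exact
stratum counts are not enforced). Sex and family history are thresholded to
0/1 at 50% and 30% prevalence. Metabolites stay on the standardized scale,
mirroring per-metabolite standardization of assay data. Rows that would be
diabetic at baseline (FPG ≥ 7.0 or 2-h PG ≥ 11.1 mmol/L) or carry a
nonpositive glucose value are redrawn by rejection, which perturbs the
glucose correlations only marginally (the recovery test bounds the total
distortion). Missingness is injected completely at random per marker
(defaults: 2% for metabolites and insulin, 1% HbA1c, none for glucose and
clinical variables); the real missingness mechanism of such cohorts is
unknown, so MCAR is an explicit simplification.

**What passing tests show — and don't.** The generator matches first- and
second-order structure (group separations, pairwise correlations, strata)
but its joint distribution is a thresholded/truncated Gaussian copula. Real
cohorts have skewed insulin distributions, nonlinear marker–glucose
relationships, informative missingness and measurement batch effects, none
of which are emulated. Passing the recovery and calibration tests therefore
validates the *pipeline machinery* — enumeration, leakage-free CV, DeLong
inference, FDR control — under known ground truth; it does not reproduce,
and cannot be used to claim, the AUC values of any real cohort, whose raw
data are not publicly deposited.

## Numerical choices and degenerate inputs

* Standardizing a constant vector is an error, never silent zeros; a
  constant feature inside a CV training fold is left unscaled (scale 1).
* `fisher_exact` uses the "sum of hypergeometric probabilities ≤ observed"
  two-sided convention (verified against full enumeration for tables with
  total ≤ 48).
* Singular systems at λ = 0 raise; any positive λ regularizes them.
* Sets of markers are canonically sorted, so model identity, deduplication
  and run determinism are independent of declaration order.
* Results tables are written with fixed formatting (`%.6g`), making repeat
  runs byte-identical for a given configuration and seed.
* Seeds: every stochastic component (cohort draw, fold shuffles, bootstrap)
  descends from an explicit integer seed through `numpy` `SeedSequence`;
  model-level seeds are derived from the master seed and the model's
  position in the canonical enumeration.

## Problem sizes used by the shipped checks

The test suite exercises the pipeline at the sizes where each property is
sharp: correlation and effect recovery at n = 20 000 (Monte-Carlo band
±0.03/±0.02), nested-CV calibration at n = 400–5000 with 10–20 repetitions,
type-I error with 2000 simulated comparisons at n = 200, and the end-to-end
determinism check on the emulated 543-participant cohort with a 50-model
grid at 10 repetitions. The full default grid (1353 unique models after
deduplication across families) runs with the complete 100-repetition
protocol in under two hours on one CPU; the reduced-repetition settings in
the tests estimate the same quantities with proportionally wider Monte-Carlo
bands.

## Known limitations

* The default grid documents its own deduplicated total (1353); the exact
  composition of the published 1527-model benchmark is defined in
  supplementary material that is not machine-readable here, so the grid is
  shipped as configuration rather than as an assertion of that count.
* Insulin is emulated on a single assay scale; no RIA/enzyme-immunoassay
  conversion is attempted. HbA1c is treated as a generic numeric marker
  (no %-to-mmol/mol conversion).
* Only baseline markers and a fixed-horizon binary outcome are modelled; no
  longitudinal trajectories, no time-to-event structure, no partial or
  time-dependent ROC.
* The choice to impute only metabolites by minimum (clinical and glucose
  variables complete-case) reflects the two missingness policies stated for
  the emulated study design; whether clinical variables were also imputed
  there is ambiguous, so the split is configurable
  (`RunConfig.impute_metabolite_columns`).
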