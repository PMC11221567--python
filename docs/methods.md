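# Methods

## Problem setting

A fixed classifier has been evaluated on a held-out cohort, producing one
record per evaluation unit: protected group A (two groups, typically with
strong imbalance), true class Y, predicted class Ŷ, and for binary tasks a
score in [0, 1]. The package post-processes these predictions to satisfy a
fairness criterion and quantifies subgroup disparity before and after. The
binary task contrasts no-cancer with advanced-stage cancer; the three-class
task splits stages into 0 / I–II / III–IV. Evaluation units are individual
prediction records; aggregation across slides or biopsies belonging to one
patient is out of scope.

## Rates and epsilon regularization

Per group, FPR = FP / (FP + TN + ε) and TPR = TP / (TP + FN + ε) with
ε = 0.001 by default. The ε sits once in each denominator — the minimal
change that keeps rates finite when a small group has no negatives or no
positives (a 9-record group can easily have zero positives in a half
sample). The alternative convention of adding ε to each of the four counts
is available via `epsilon_mode="counts"`; it shifts empty-cell rates to 1/2
rather than 0 and is not the default. Whenever a denominator is at least 1,
the regularized rate is within 1e-3 of the exact ratio, so reported rates
are never distorted beyond the third decimal.

Fairness gaps are the largest absolute between-group differences: equal
opportunity over TPR only, equalized odds over both TPR and FPR, so the
equal-opportunity gap never exceeds the equalized-odds gap. Performance
summaries use the positive-class convention for binary precision/recall/F1
and macro averaging for K > 2 (each stage class weighted equally, robust to
the strong class imbalance); accuracy is reported in percent.

## Derived predictors

### Binary

Decision variables are the per-group mixing probabilities
p_α = (Pr(Ŷ_adj=1 | Ŷ=0, A=α), Pr(Ŷ_adj=1 | Ŷ=1, A=α)). The adjusted rates
are linear in p — e.g. TPR_adj(α) = p_α0·Pr(Ŷ=0|Y=1,α) + p_α1·Pr(Ŷ=1|Y=1,α)
— so the achievable operating points form the convex quadrilateral spanned
by (0,0), the base point, its label-flipped complement and (1,1): the ROC
convex hull of the available predictors (score-threshold points extend the
hull when scores are present). Equalized odds imposes two linear equalities
per group pair (common FPR and TPR), equal opportunity one (common TPR). The
objective is the expected loss weighted by the empirical joint
Pr(A, Y, Ŷ); the default 0–1 loss can be replaced by group-dependent
penalties l(i, j, α). The program is solved with HiGHS via
`scipy.optimize.linprog`.

The program is always feasible — constant predictors (p0 = p1) realize any
point on the chance diagonal for every group simultaneously. If the solver
nevertheless fails numerically, the fit falls back to the better of the two
diagonal endpoints and sets an explicit `infeasible` flag; the fallback is
never silent. Groups with no mass at Y = 0 or Y = 1 have undefined
conditionals; their constraints are dropped as vacuous and the group is
listed in `degenerate_groups`.

### Multi-class

Each group carries a column-stochastic matrix
W^α[i, j] = Pr(Ŷ_adj = i | Ŷ = j, A = α). The fit minimizes the adjusted
predictor's expected loss

E[l] = Σ_α Σ_{i,j,k} l(i,j,α) · W^α[i,k] · Pr(Ŷ=k, Y=j, A=α),

subject to column sums of 1, entries in [0,1], and the criterion's equality
constraints on the adjusted conditionals
Pr(Ŷ_adj=i | Y=j, A=α) = Σ_k W^α[i,k]·Pr(Ŷ=k | Y=j, A=α). Equalized odds
ties all (i, j) pairs across groups; equal opportunity — which has no single
canonical multi-class definition — is implemented as the per-class
generalization of equal TPR: only the correct-classification probabilities
(i = j) are tied. A consequence worth knowing: at K = 2 this per-class
relaxation fixes both the TPR and 1−FPR, collapsing to equalized odds, so it
is *stricter* than the binary TPR-only criterion; the K = 2 reduction
consistency guarantee (multi-class fit ≡ binary fit to 1e-6 in objective)
therefore applies to equalized odds. Constraints touching zero-mass
(Y = j, A = α) cells are dropped as vacuous rather than ε-inflated: the ε
belongs to rate reporting, not to the LP's probability mass.

The loss-minimization literature this construction follows writes the
objective with the adjustment matrix conditioned on the base prediction but
weighted by the true-label marginal; taken literally that mixes the Ŷ and Y
indices. The triple-sum objective above is the coherent expected loss of the
adjusted predictor and is what the package optimizes and reports.

### Tie-breaking and stochastic application

LP optima are often non-unique (e.g. when a constant predictor and a mixture
achieve the same loss). A second-stage LP restricts to the optimal face
(objective pinned within 1e-9) and minimizes the L1 distance to identity
mixing / identity matrices. L1 rather than a quadratic distance keeps the
tie-break inside linear programming; any deterministic convex tie-break
would serve, and L1 gives reproducible solutions across solver backends.

Adjusted labels are *sampled* from the fitted conditionals rather than
arg-maxed — the fairness guarantees hold for the randomized predictor, and
thresholding would break them. Application is deterministic given the seed.

## Bootstrap evaluation

50 iterations; each draws ⌊n/2⌋ records from the pooled table without
replacement, preserving the natural group imbalance within each subsample,
then recomputes per-group ε-regularized rates. Draws are without replacement
because the scheme selects "a subset of half the records"; with-replacement
resampling is available via `replace=True`. A group absent from a subsample
contributes a missing replicate, excluded from summaries and counted in
diagnostics. Confidence intervals default to the normal approximation
mean ± z·SD/√iterations at 95% (percentile intervals via
`ci_method="percentile"`). Between-group comparison uses a Student
(pooled-variance) two-sided t-test on the replicate vectors, Welch via
`equal_var=False`.

Caveat: half-sample replicates from one fixed table are correlated, so this
t-test understates dependence and is a descriptive disparity score, not a
calibrated test. It is implemented in exactly this form for comparability with the evaluation scheme it mirrors; a
permutation test on the raw records (`permutation_pvalue`) is provided as a
clearly separate alternative.

## Synthetic cohort generator

The generator emulates the prediction-level structure the analysis assumes,
not images or model internals.

Binary: per group, Y ~ Bernoulli(prevalence); latent score z ~ N(0, 1) for
Y = 0 and N(d′, 1) for Y = 1 with d′ = √2·Φ⁻¹(AUC); reported score is the
logistic squash expit(z) (monotone, hence AUC-preserving);
predicted label = score > threshold. This gives closed-form control of group
AUC and of the operating point at any threshold:
TPR = Φ(d′ − logit(t)), FPR = Φ(−logit(t)), inverted by
`auc_for_tpr_at_threshold` when a target TPR is wanted. Group sizes are
deterministic (largest-remainder rounding of the configured fractions) so
fixed designs such as 32/9 out of 41 reproduce exactly. Multi-class: the
generator is parameterized directly by per-group row-stochastic confusion
tendencies Pr(Ŷ | Y) — exactly the conditionals the multi-class adjustment
consumes, which makes parameter recovery directly testable.

All randomness flows through one root seed with named per-stage substreams
(CRC-32 of the stage name folded into a `SeedSequence`), so cohort
generation, stochastic application and bootstrap subsampling are
independently reproducible.

Default study conditions: two groups with strong imbalance (78/22, or the
fixed 32/9 evaluation design), positive prevalence 0.39 (binary) and class
mix 0.18/0.66/0.16 (three-class) matching the held-out stage distributions
of the motivating setting; group AUCs 0.80 vs 0.65 at threshold 0.7, which
yields a pre-adjustment TPR gap of ≈ 0.25 — a disparity of the direction and
order the motivating setting reports. The three-class confusion defaults
(diagonals ≈ 0.75–0.80 vs 0.50–0.55) encode the same strong-vs-weak
pattern. What the generator does not emulate: within-patient correlation
between slides, covariate shift between fit and evaluation data, label
noise, and calibration structure in the scores beyond the binormal family —
so passing tests demonstrate the correctness of the adjustment machinery
under the assumed sampling model, not robustness of fairness conclusions on
real slide data.

A note on degenerate optima: with the three-class study conditions (majority
class at 0.66, weak minority-group classifier) the 0–1-loss equalized-odds
optimum is the constant majority-class predictor — fair by construction,
with expected loss 1 − 0.66. This is a real property of equalized-odds
post-processing on weak classifiers, not an artifact; group-weighted losses
in `LossSpec` are the lever for steering away from it.

## Numerical choices and problem sizes

- Solver: HiGHS (`scipy.optimize.linprog`); constraint residuals and
  column-stochasticity of returned solutions are verified to 1e-6.
- Fit-time equality of adjusted rates across groups: 1e-6 tolerance.
- Joint distributions must carry total mass 1 within 1e-9; configured
  probability vectors must sum to 1 within 1e-9 (confusion rows: 1e-6).
- Fitting and application use the empirical joint of the supplied table; the
  package applies fitted predictors to fresh samples in its own validation,
  where constraint satisfaction degrades only by sampling error
  (O(1/√n) in the relevant conditional cell counts).
- Validation problem sizes: 100000 records per group for population-level
  constraint checks (conditional-rate gaps ≤ 0.01–0.02), 10000 per group for
  generator parameter recovery (±0.02), grid oracles at step 1e-3 (objective
  agreement within 2e-3), 10⁶ sampled feasible points per instance for LP
  dominance checks.

## Limitations

- One protected attribute, two groups exercised end to end (the constraint
  machinery generalizes to more groups against a reference group, untested
  beyond two).
- Label-level adjustment only; no score-vector (probability) post-processing.
- The bootstrap t-test caveat above: treat its p-values as descriptive.
- Fitting and evaluating on the same held-out table (the default when no
  separate calibration split is supplied) reuses data; the honest
  generalization check is the fresh-sample route the validation uses.
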