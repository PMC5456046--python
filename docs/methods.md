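# Methods

## Model

We consider binary classification with labels Y ∈ {0,1}, the minority
class coded 1, and deterministic classifiers θ: X → {0,1}. Writing
π = P(Y=1), γ = P(θ=1) and TP = P(Y=1, θ=1), the Matthews correlation
coefficient of θ against Y is

    MCC(θ) = (TP − γπ) / √(γ(1−γ) π(1−π)),

equivalently the Pearson correlation of the two binary variables, or the
familiar confusion-matrix expression on sample counts. The MCC is
undefined when any marginal sum of the confusion matrix is zero
(equivalently γ ∈ {0,1} or π ∈ {0,1}); the package returns value 0 with
`defined=False` in that case. The fallback keeps constant classifiers
tabulable in sweeps; callers who need strictness can inspect the flag.

The population-optimal classifier has thresholded form
θ*(x) = sign[(TP − γπ)(η(x) − δ*)] with η(x) = P(Y=1|X=x) and
δ* = (TP* + γ(π − 2TP*)) / (2γ(1−γ)), where the starred quantities are the
optimum's own rates. This presumes a continuity condition on the
distribution of η(x) given each class at the point δ* (satisfied in
particular when η(X)|Y is continuous); the condition is a hypothesis on
the data distribution, documented here, and is not checkable from samples
nor enforced at runtime.

## Estimation

Since δ* is defined through the optimum itself, estimation proceeds by
plug-in and search (`fit_mcc_classifier` / `MCCClassifierModel.fit`):

1. stratified split of the training sample into disjoint halves S1/S2
   (default 0.5/0.5; the fraction is configurable);
2. η̂ fitted on S1 by L2-penalized logistic regression (inverse penalty
   C = 1.0, lbfgs, up to 1000 iterations). Log loss is a proper loss,
   which is the condition under which the procedure is consistent. The
   estimator is pluggable behind the `ProbabilityEstimator` contract —
   anything with `fit` / `predict_proba1` trained on a proper loss
   qualifies;
3. for every δ on a grid (default 0.01…0.99, step 0.01 — finer than the
   MCC differences resolvable at practical n) both oriented rules
   1[η̂ > δ] and 1[η̂ < δ] are scored on S2 by sample MCC, with all
   empirical quantities (TP, γ, and the prevalence π) taken from S2, so
   the objective is a function of a single sample;
4. the maximizer is returned. Exact ties prefer orientation +1, then the
   smallest δ. A prediction tie η̂(x) = δ yields label 0. The returned
   rule keeps the S1-fitted estimator; refitting on S1 ∪ S2 after
   threshold selection is available (`refit=True`) but off by default, so
   the returned object is exactly the rule that was validated on S2.

The `fit_bayes` baseline fits η̂ on all the data and fixes δ = 0.5,
orientation +1.

Undefined MCC values arising inside the grid search (e.g. a δ beyond the
range of η̂ on S2) score 0, which only matters when every candidate is
degenerate.

## Exact certification on discrete domains

On a finite domain of K points with marginal μ and conditional η, every
one of the 2^K labelings has exact population rates
TP = Σ μ(x)η(x)θ(x), γ = Σ μ(x)θ(x), π = Σ μ(x)η(x). `exhaustive_optimal`
scores them all (guarded to K ≤ 24; ties resolve to the lexicographically
smallest bit vector; the all-0 and all-1 labelings are excluded as
undefined). `theorem_classifier` sweeps thresholds at the midpoints
between consecutive distinct η values (plus one candidate below the
minimum and above the maximum — population MCC is piecewise constant in
δ, so midpoints exhaust the thresholded family), over both orientations,
and additionally recomputes δ* from the winner's rates via the closed
form, reporting whether re-thresholding at δ* reproduces the same
labeling (`self_consistent`). Agreement of the two maxima to 1e−12 on
random draws is the optimality certificate; the two routes share no code
beyond the MCC formula.

Random populations draw μ from normalized Uniform(0,1) values and set
η(x) = 1/(1+exp(−wx)) with a single weight w ~ N(0,1), x = 1…K. η is then
monotone, never exactly constant, and the draw is a pure function of the
seed.

## Simulation studies

**Robustness to imbalance.** For each class proportion π on a grid
(default 0.05…0.45, step 0.05 — the range where class 1 is the minority)
and n = 10,000: a training label draw fixes the empirical prevalence
available to three feature-blind baselines (C1: stratified random
predictions at rate π̂; C2: constant majority label; C3: fair coin), and
an independent test draw of the same size is scored on MCC, AUC, plain
accuracy, balanced accuracy and F1. Train and test are separate draws so
the baselines never score against the labels that defined π̂. Predictions
are hard labels, so AUC treats them as two-valued scores with half credit
for ties — equivalently (TPR+TNR)/2; its null sd is therefore
0.5·√(¼/nπ + ¼/n(1−π)), which widens at small π, and the tests bound it
per-π rather than by the balanced-class 3/(2√n). The study's claim, in
testable form: the sd over the π-grid of MCC and AUC stays ≤ 0.02 for all
three baselines, while the plain accuracy of the constant classifier
swings with sd ≥ 0.1.

**Optimality.** `optimality_experiment` draws random populations
(default 20 draws, K = 10), runs both the exhaustive search and the
threshold sweep, and counts draws whose maxima agree to 1e−12. Degenerate
draws (constant η, or π ∈ {0,1}) are flagged and excluded from the
denominator with their count reported; under the generator above they
have probability zero, and the exclusion path is exercised in tests by
substitution.

**Consistency.** `generate_tabular` draws two Gaussian classes in d
dimensions (default d = 4): class 0 ~ N(0, I), class 1 ~ N(m, I) with
‖m‖ = `separation` along (1,…,1)/√d, mixing weight π for class 1. The
induced η(x) is exactly logistic in x, so the default plug-in estimator
is well-specified — the study isolates estimation error from model
misspecification. The population-optimal MCC depends only on (π,
separation): the optimal rule thresholds the scalar discriminant
s = m·x, and the optimum is computed by discretizing s onto a 4001-point
grid spanning ±8 sd around both class means (μ from the mixture density,
η from Bayes' rule) and running the oracle threshold sweep; a 200,001-
point closed-form normal-CDF sweep agrees to 4 decimals, and the value is
cached per (π, separation). `consistency_experiment` then tracks, per
training size n (default 500 / 5,000 / 50,000) and seed (default 10
seeds), the gap between the population optimum and the fitted
classifier's MCC on an independent test draw of fixed size 20,000 — fixed
so evaluation noise does not vary with n. The defaults (π = 0.1,
separation = 1.5) give a population optimum of ≈ 0.415 and a clearly
non-trivial imbalance; the expectation is a gap that is non-increasing in
n and below 0.05 at the largest n. The gap can be slightly negative at
large n (test-draw noise), which the bound tolerates.

What the generator does *not* emulate: correlated or heavy-tailed
features, label noise, non-linear class boundaries, and the
within-dataset structure of real benchmarks. Passing these studies shows
the estimation machinery tracks the population optimum when the plug-in
model is right; it does not promise the logistic η̂ is adequate for any
particular real dataset — the estimator contract exists precisely so a
better-calibrated model can be plugged in.

## Numerical choices and degenerate inputs

- Confusion counts are exact integers; all metric arithmetic is double
  precision. Population rates tolerate and clip float roundoff of order
  1e−9 from probability summation.
- The repeated-evaluation protocol (`repeat_protocol`, default 10
  repeats) redraws any round whose train or test half is single-class,
  with bounded retries and derived per-round seeds; reported sd is the
  across-repeat sample sd (ddof = 1, zero for a single repeat).
- All randomness in any experiment flows from one user-supplied seed
  through `numpy.random.SeedSequence` spawning; equal seeds give
  byte-identical tables.
- Loaders never silently recode labels: the positive class must be named
  explicitly, or minority auto-detection must be opted into (it logs the
  mapping and counts). Rows with missing values are dropped with a
  logged count; imputation is out of scope. KEEL-style `.dat` files take
  the last declared attribute as the class unless overridden, and map
  the conventional negative/positive values with positive → 1.

## Known limitations

- The exhaustive oracle is exponential by design; beyond K = 24 it
  refuses and refers to the threshold sweep (exact for the thresholded
  family, which the theory says suffices).
- Class-weighted SVM support is limited to the `class_weight_ratio`
  helper (the minority-to-majority rule for the slack-penalty ratio
  C+/C−); no SVM solver is provided or wrapped.
- Multiclass MCC, ROC-curve plotting, cost-sensitive losses other than
  the MCC objective, and continuous-domain population optima are out of
  scope.
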