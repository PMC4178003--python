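# Methods

This note documents the models and numerical choices behind `sepsipanel`:
what each stage computes, the knobs that matter, what the synthetic cohort
generator does and does not emulate, and the known limitations.

## Outcome and normalization

The outcome is a binary severity score per blood draw: 0 for the
PICU/sepsis group, 1 for the severe-sepsis group, taken as given input
(clinical category definitions are out of scope). Features are standardized
to zero mean and unit variance; the sample SD uses the n−1 denominator
throughout, including in the stored normalization parameters that travel
with every fitted model so raw measurements can be scored later. The default
protocol normalizes the full matrix before splitting, matching the study
design this package follows; a `train_only_norm` variant recomputes
parameters on training rows only for users who want the leakage-safe
version. Missing values are rejected at load — no imputation is attempted.

## Canonical-correlation subset selection

With a one-dimensional outcome the first canonical correlation between a
feature subset S and y equals the multiple correlation coefficient,
√R² of the OLS regression of y on X_S with intercept. The implementation
precomputes the centered cross-product matrices once and solves, for every
subset, the k×k normal-equation system; subsets of one size are solved as a
single batched `numpy.linalg.solve` call, with a per-subset pseudo-inverse
fallback (relative singular-value cutoff 1e−10) on rank deficiency. R² is
clipped to [0, 1] against roundoff. Full enumeration at p = 19 touches
2¹⁹ − 1 ≈ 5.2×10⁵ subsets and completes in a few seconds on one CPU.

Ties are broken by the lexicographically smallest feature-index set (the
enumeration order), which makes traces deterministic. The stepwise trace
reports, per k, the best subset, its correlation, and the entering/leaving
features relative to k−1; multiple entries per cell are legal, since the
best subsets need not be nested. Greedy forward selection (add the single
best feature, never remove) is provided for comparison; the test suite
includes a suppressor construction on which the two provably diverge.
Correlation with the binary outcome uses the 0/1 coding as assigned, with
no class re-weighting.

## Class-weighted 1-norm SVM

The classifier solves

    min ‖w‖₁ + C₊ Σ_{i: y_i=+1} ξ_i + C₋ Σ_{i: y_i=−1} ξ_i
    s.t. y_i (w·x_i + b) ≥ 1 − ξ_i,   ξ_i ≥ 0,

as a linear program via the split w = w⁺ − w⁻ (2p + 1 + n variables, n
margin rows), using scipy's HiGHS backend. The offset b is free and
unpenalized. The penalty convention is C₊ = N₋/N₊ and C₋ = 1 — the
prevalence-balancing rule with the positive (severe, usually minority)
class up-weighted; the convention is recorded in every serialized model and
can be swapped via a flag. Weights with |w_j| < 1e−8 are truncated to
exactly zero, so sparsity statements are exact. The test suite checks the
optimum against an independent epigraph-formulation LP to 1e−6.

The published decision function is shipped as an immutable fixture (means,
SDs, weights and weight standard errors for Ang-2, Ang-1, HCO3). No
intercept was published, so the fixture's bias is **fixed at 0 by
decision**; every scored output derived from it inherits that choice. A
SHA-256 digest of the fixture is pinned in the test suite against silent
drift. Classification uses the published boundary rule: severe iff
Score ≥ 0 (the boundary itself is severe).

## Bagged evaluation

One evaluation repeat draws a uniform random test third (round(n/3) rows),
trains B = 50 L1-SVMs on bootstrap resamples of the remaining two-thirds
(resample size = training size; single-class resamples are redrawn, up to
100 times), and aggregates by averaging weight vectors and biases — for
linear decision functions the mean of the decisions equals the decision of
the means, exactly. Measures on the held-out third are TPR, TNR, PPV and
NPV; a zero-denominator measure is reported as NaN, excluded from the mean,
and counted, never silently zeroed. The procedure repeats R = 100 times
with fresh splits (each repeat redraws the test third); reported values are
means with standard errors SD/√R over the defined repeats. R = 1 yields a
flagged degenerate result (SE = NaN). Measure-versus-k curves reuse the
same seeded split sequence at every k (a paired design), so each row equals
a standalone `repeated_evaluation` and differences across k are not
confounded by split noise. Splits are by row (draw); repeated draws of one
patient can land on both sides — see Limitations.

## Random-forest importance

The forest grows CART trees (scikit-learn `DecisionTreeClassifier`: Gini
criterion, grown to purity, floor(√p) candidate features per split) on
bootstrap resamples drawn here, so each tree's out-of-bag rows are explicit.
The importance of feature j is the OOB permutation measure: per tree, the
accuracy on its untouched OOB rows minus the accuracy after permuting
feature j's OOB values; the mean over trees is the mean decrease in
accuracy (MDA). A feature no tree splits on gets exactly 0 (permutation
cannot change any prediction). Gini importance is computed for reference
but ranking uses MDA. The default forest size is 1000 trees; importance
tests use 150–500 trees, which is ample for the rank separations checked.
OOB error uses per-sample majority vote over the trees that held the sample
out.

## The synthetic cohort generator

The real cohort was never deposited, so all statistical tests run against a
generator that emulates its structure. Defaults were fixed once, during
generator design, by matching the qualitative selection structure the
original study reports (strongest single marker Ang-2; best triple
{Ang-2, Ang-1, HCO3}; derived ratio and electrolytes selected late; noise
columns last); they are configuration, not fitted quantities.

**Sampling frame.** 45 patients, 40% severe; draws follow the study
schedule (2/day on days 1–3, 1/day on days 4–7, max 10) with per-draw
discharge probability 0.08 (geometric attrition). Draws are independent
given group and day.

**Within-draw model.** A latent Gaussian vector with group-specific
correlation: an equicorrelated electrolyte block (Na, K, Cl, HCO3) at
ρ = 0.96 (non-severe) / 0.30 (severe), the Ang-1/Ang-2 pair at 0.21 / 0.76,
other coordinates independent. Configured correlations are latent; implied
covariance blocks are validated positive semi-definite at construction.
Skewed positive analytes (Ang-1, Ang-2, VEGF, BUN, Cr) exponentiate their
latent coordinate (log-normal with the configured raw mean and SD); the
Ang-2/Ang-1 column is the elementwise ratio of the drawn values; g-Noise
and u-Noise are independent standard-normal and uniform(0,1). Ang-2, Ang-1
and HCO3 marginals use the published score's means and SDs so the generator
and the fixture share units.

**Severity effects.** Severe-group effects are raw-scale standardized mean
shifts (in units of the variable's SD) — the scale in which the original
study's power calculation is phrased. The panel carries the strong effects:
Ang-2 +1.80 (within the 1.5–1.8 SD range the study was powered to detect),
Ang-1 −0.63, HCO3 −0.90. Every other clinical variable carries a weak shift
(|0.30–0.45| SD): admission mortality risk up, platelets/hemoglobin down,
renal markers up, and electrolytes co-depressed with HCO3 at −0.40 —
proportionate co-movement that reflects how acidosis perturbs the whole
electrolyte panel rather than bicarbonate in isolation. The noise columns
carry exactly zero effect. Weak effects matter: in real data nearly every
clinical variable is weakly associated with severity, and without them the
noise columns would be statistically exchangeable with 14 clinical
variables and could not rank last.

**Treatment-response decay.** The Ang-2 shift is multiplied by
0.5^(day − 2) after day 2, driving the longitudinal score collapse (Ang-2
dominates the published score). Other effects persist through the week:
admission variables do not change, and organ-injury markers and Ang-1
recover on slower time scales than the one-week window. The decay day and
factor are configurable.

**What passing tests do and do not show.** The generator reproduces the
correlation skeleton, effect directions, schedule and attrition — enough to
exercise every pipeline stage and to make planted-recovery statements
meaningful. It does **not** model within-patient serial correlation
(draws are conditionally independent), measurement error or assay floors,
mixed infection etiologies, or treatment covariates; absolute performance
numbers on synthetic cohorts (e.g. TPR ≈ 0.97) are therefore optimistic
relative to any real cohort, and only the structural/relative statements
(panel recovery, noise demotion, sign patterns, trajectory shape) transfer.

## Numerical choices

- Normalization: ddof = 1 everywhere; constant columns are an error.
- Subset search: batched Cholesky-backed solves; pseudo-inverse fallback at
  rcond 1e−10; R² clipped to [0, 1]; trace monotonicity asserted to 1e−8.
- LP: HiGHS defaults (feasibility/optimality ~1e−8); weight truncation
  1e−8; objective cross-checked to 1e−6.
- Splits: round(n/3) test rows; n < 3 is an error. Single-class splits and
  bootstrap resamples are redrawn with a bounded retry budget and counted.
- Determinism: every stochastic routine takes a seed; identical seeds give
  byte-identical outputs (cohorts, traces, ensembles, forests).
- Test problem sizes (450-draw cohorts, 150–500 trees, B ≤ 50, R ≤ 50 in
  statistical tests; R = 100 in the acceptance script's ensemble run) were
  chosen so the checked separations are far from their thresholds while the
  whole suite stays interactive.

## Limitations

- The published-score fixture has no intercept (none was published); all
  fixture-based scores assume b = 0.
- HCO3 inherits the published pooled SD (24.361 mmol/L), which is large
  relative to its mean; synthetic bicarbonate values can occasionally be
  non-physiologically small or negative. The severe-group Ang-1 mean
  (−0.63 SD) is likewise lower than typical reported cohort medians; both
  are prices of keeping the generator on the published scale.
- Row-level splitting ignores the repeated-measures structure; a by-patient
  split option is a natural extension but is not claimed to be the original
  protocol.
- Exhaustive enumeration is exponential in p; beyond p ≈ 25 the search is
  impractical by design.
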