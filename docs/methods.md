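# Methods

## Problem and estimand

The package estimates the average treatment effect (ATE)
Δ\* = E[Y(1) − Y(0)] from a cohort of N i.i.d. subjects in which the
binary treatment A and (binary, or bounded) outcome Y are jointly
observed only on a small labeled subset (indicator R, missing
completely at random with labeling rate ρ → 0 as N grows while
n = ρN → ∞), while confounders X and error-prone surrogate scores S —
the kind of phenotyping-algorithm output an EHR pipeline produces —
are observed for everyone.  Identification rests on the standard
causal triple for the labeled data: consistency, positivity
(1/M ≤ P(A=1|X) ≤ 1−1/M), and ignorability Y(a) ⫫ A | X; the labels
are MCAR by design (random chart-review sampling).

## The semi-supervised estimator

Write π(a,x)=P(A=a|X=x), μ(a,x)=E[Y|A=a,X=x] for the confounder-side
models and Π(a,w)=P(A=a|W=w), m(a,w)=E[Y|A=a,W=w] for the imputation
models on the full vector W=(X,S).  Starting from the complete-data
efficient influence function φ_cmp (the AIPW summand), the
semi-supervised influence function is

    φ_SSL = E[φ_cmp | W]  +  (R/ρ) (φ_cmp − E[φ_cmp | W]),

and plugging the logistic/regression forms of the conditional
expectation gives the per-subject influence value V_i implemented in
`smmal.estimator.influence_values`.  The estimator is the mean of the
cross-fitted V_i over all N subjects; its variance estimate is
ρ̂ × the empirical variance of V_i over all N (both the labeled-set
uncertainty and the finite-unlabeled-set uncertainty are captured),
and intervals use normal quantiles on the √n scale.  ρ is not
observable; we plug in ρ̂ = n/N everywhere (√N-consistent under MCAR);
an external ρ can be passed when the sampling fraction was designed.

Two exact algebraic facts anchor the implementation and are asserted
in tests: with R ≡ 1 and ρ = 1 the imputation terms cancel and the
estimator reduces to the complete-data cross-fitted AIPW to machine
precision; and the imputation models need not be correct — wrong Π̂, m̂
only cost efficiency, never validity (coverage is tested under
deliberately constant imputations).

Comparators: the supervised estimator (labeled-only cross-fitted
AIPW/DML), the unsupervised estimator (surrogates dichotomized at the
quantile matching the labeled prevalence and treated as truth), crude
arm-mean differences, and the optimal linear ensemble of the
semi-supervised and supervised estimators with weight
b̂ = (V̂_ssl − Ĉ)/(V̂_ssl + V̂_sl − 2Ĉ) from the estimated influence
vectors (falling back to the semi-supervised estimate when the
denominator degenerates).

## Cross-fitting

The whole cohort — labeled and unlabeled together — is split into K
folds (default K=10; the high-dimensional pipeline defaults to K=5,
the value used in the motivating application); every subject's
nuisance values come from fits that never saw their fold.  The
high-dimensional route adds a second level: for each ordered fold pair
(k1,k2) an initial fit trained on the out-of-two-folds labeled rows is
applied to fold-k2 rows inside the calibrated objective targeting fold
k1, so no calibration weight ever involves a fit that saw the row
itself or the target fold.  A fold draw whose labeled out-of-fold (or
out-of-two-folds) subset lacks a treatment arm is re-drawn with an
incremented seed, up to 20 times, then rejected with a diagnostic —
the degenerate case is a data problem, not a fitting problem.

## Low-dimensional nuisances: tensor-product B-splines

All four nuisance models are first-order (piecewise-linear) B-spline
logistic regressions with equally spaced interior knots on the
training range (out-of-range points are clamped to the boundary).
The number of degrees of freedom is chosen by 10-fold CV on the
out-of-fold entropy; 1-D candidates run over 1..⌊√n⌋ (22 at n=500),
ties to the simpler model.  For tensor bases the same degree is used
in each dimension and the candidate list is capped so the basis
dimension stays below a quarter of the training rows — a 3-D cube at
degree 22 would have 12k parameters for 500 labels, which no
cross-validation would survive.  Degree selection runs once per model
on the full labeled set (the stability of CV at n=500 versus n=450 is
far below its replicate-to-replicate noise); the coefficient fits are
then re-estimated per fold on out-of-fold data, which is what the
cross-fitting guarantee needs.  Fitted probabilities are truncated to
[g(−M), g(M)] with M = 2.2, i.e. [0.1, 0.9] — the bounded-estimator
contract that keeps every inverse-probability weight below 10.
Probabilities (not linear predictors) are clipped; under the monotone
logistic link the two are equivalent.

The logistic fits use a hand-written IRLS (Newton) loop with a 1e-8·n
ridge jitter and a ±30 linear-predictor clamp, batched across CV folds
for speed; a separated fit (e.g. a constant-outcome arm) simply runs
to its clamp and is then truncated, which is the behavior the bounded-
estimator contract prescribes.  Accuracy against statsmodels GLM is
part of the test suite.

## High-dimensional nuisances: calibrated lasso with truncation

Under logistic models for all four nuisances, the pipeline is:
imputation lassos (A on W; Y on W within arm) and initial
propensity/outcome lassos (on X) as plain L1-penalized logistic fits;
then per-arm *calibrated* fits whose losses are chosen so that the
first-order conditions kill the first derivative of the ATE estimate
with respect to the other model (Neyman orthogonality):

* calibrated propensity (arm a):
  mean of  ġ(τ(xᵀβ_init)) · [ (a−A) xᵀα + 1{A=a} e^{(−1)^a xᵀα} ],
* calibrated outcome (arm a, labeled arm-a rows):
  mean of  e^{τ((−1)^a xᵀα_init)} · ℓ_logistic(Y, xᵀβ),

with τ(x) = sign(x)·min(|x|, 2M) the linear-predictor truncation.  The
initial-fit weight multiplies **both** terms of the propensity loss;
this is the reading under which the population minimizer is the true
coefficient vector when the propensity model is correct and under
which the orthogonality derivative vanishes (both verified in tests; a
weight on the linear term alone satisfies neither).  The arm-0 loss
identifies the same coefficient vector; its prediction uses the
negated linear predictor, so the two per-arm propensity estimates need
not sum to one.  The treatment imputation for a=0 is taken as the
binary complement of the a=1 prediction.  Truncation bounds every
calibration weight in [e^{−2M}, e^{2M}] no matter how wrong (or dense)
the initial fit is — this is what removes any sparsity requirement on
a mis-specified initial model.  Final predictions:
π̂(1,x)=g(τ(xᵀα̂₁)), π̂(0,x)=g(τ(−xᵀα̂₀)), μ̂(a,x)=g(xᵀβ̂_a),
Π̂(1,w)=g(wᵀξ̂), m̂(a,w)=g(wᵀζ̂_a).

Solver.  One proximal-Newton coordinate-descent handles all three
convex losses (the exponential-tilt propensity loss is not a GLM
family in any installed package).  Numerical choices: intercept
unpenalized; KKT certification at 1e-6 (1e-5 inside CV paths);
active-set cycling with periodic full sweeps; objective-based step
halving (the exponential tilt is convex but not Lipschitz-smooth);
exponent arguments clamped at ±30 with a counted diagnostic; and
explicit divergence detection — below a data-dependent penalty level
the exponential-tilt objective is genuinely unbounded (a margin
direction exists), the iterate blow-up is detected and that λ and all
smaller ones are excluded from the CV path.  Penalties are selected by
cross-validation of the *same* loss along a 50-point log-spaced path
from the data-driven λ_max (which scales like the √(log p / n) theory
rate for standardized designs), warm-started, ties to the stronger
penalty; one CV per model class per cohort, reused across folds
(fold-to-fold training sets differ by <10% in size, far less than the
CV noise).  Columns are standardized on the full cohort (W is fully
observed, so this is ancillary under MCAR) and coefficients
de-standardized for reporting.

## Synthetic cohorts

The generator reproduces two designs.  Low-dimensional smooth:
X ~ U(0,1), π\*(1,X) = μ\*(1,X) = 1 − 1.2/(3 − X²),
μ\*(0,X) = 1 − 1.2/(3 − (1−X)²).  The printed form of this curve is
typographically ambiguous; the adopted grouping is the one that
respects positivity (probabilities stay in (0.4, 0.6) / (0.7, 0.87)),
and the alternative admissible reading 1 − 1.2/(3 − X)² is available
as `smooth_form="shift_sq"` and recorded in output metadata.  Under
either reading μ\*(0,·) is the treated curve at 1−X, so the true ATE
is exactly 0 by symmetry.  High-dimensional: X is AR(1) Gaussian
(X₁=U₁, X_j = 0.5X_{j−1} + 0.75U_j; stationary variance 0.75) with
sparse logistic propensity/outcome models at graded signal strengths
0.5/0.25/0.125/0.0625 and second-order-interaction variants read as
g(linear × (1 + interaction)) — fitting linear lassos against the
interaction truths creates the mis-specification scenarios.  The true
ATE of the high-dimensional outcome models is a 10⁶-draw Monte-Carlo
oracle stored with its standard error; recovery tests use
max(3·SE, 0.002).

Surrogates: S = Beta(α+u, 1) when the latent label is 1 and
Beta(1, α+u) when 0, with u = X (low-d) or Φ(X₁) (high-d), both
U(0,1) marginally so the α↔AUC calibration transfers.  `ALPHA_TABLE`
stores the per-setting concentrations for AUC
0.80/0.90/0.95/0.99/0.999 as calibrated per setting (the small
per-setting differences are kept verbatim).  `surrogate_auc` checks
the calibration two ways: rank (Mann–Whitney) AUC on a simulated
cohort, and the conditional closed form
P(Beta(a,1) > Beta(1,b)) = 1 − a·B(a, b+1) averaged over case/control
covariate draws.

One named RNG substream per component (X, A, Y, S_A, S_Y, R) makes
cohorts bitwise reproducible and lets a single design knob perturb
only its own stream.  What the generator does *not* emulate: real
phenotyping scores are not Beta-distributed, codes arrive as counts
with informative missingness, true confounders are mixed-type and
collinear, and real labels are rarely perfectly MCAR.  Passing tests
therefore certify the estimator's statistical properties under the
stated models, not performance on any particular EHR.

## Benchmark harness and problem sizes

`run_replicates` re-generates the design per replicate (seeds
base_seed + r), runs every requested estimator on the same cohort
(common random numbers make relative-efficiency ratios stable at
moderate replicate counts), and reports bias, empirical SD, mean SE,
CI coverage against the design's true ATE, and relative efficiency as
the ratio of empirical variances.  Default scales, chosen as a
desk-scale study: low-dimensional batches at N=10,000, n=500, K=10,
200 replicates; high-dimensional batches at N=5,000, n=500, p=100,
K=5, 5-fold penalty CV, 100 replicates per scenario; the unsupervised
benchmark uses the 1..22 degree candidate list of the simulation
recipe.  Coverage bands in tests are exact binomial intervals at the
realized replicate count.

## Known limitations

* Binary outcomes only in the high-dimensional route (a linear-OR
  calibration would need a different weighting scheme).
* MCAR labels only; under MAR the labeling propensity would become a
  fifth nuisance with its own calibration requirements.
* The efficiency gain is adaptive: with uninformative surrogates the
  estimator matches (not beats) the supervised one, and wrong
  imputations push the relative efficiency toward 1.
* The unsupervised benchmark is implemented for comparison; its
  intervals undercover by construction whenever the surrogates carry
  classification error, and it should not be used for inference.
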