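# Methods

## Model

Trial-wise voxel activation is modelled as a linear combination of seven
latent factors:

β[s,t,v] = w_task_g·f_task_g[v] + w_rt_g·f_rt_g[v]·RT[s,t] + w_conf_g·f_conf_g[v]·conf[s,t]
         + w_task_s·f_task_s[s,v] + w_rt_s·f_rt_s[s,v]·RT[s,t] + w_conf_s·f_conf_s[s,v]·conf[s,t]
         + w_noise·ε[s,t,v]

Assumptions:

* All latent factors and the noise are i.i.d. standard normal — group
  factors drawn per voxel, subject factors per subject × voxel, noise per
  subject × trial × voxel.  The noise has unit variance by construction;
  w_noise is its scale and is fixed to 1 in the fitting protocol, making the
  six free weights interpretable in noise-SD units.
* RT and conf are the z-scored behavioral values of the trial.  Z-scoring is
  per subject over all of that subject's trials, with the sample (n−1) SD;
  behaviorally constant subjects get all-zero regressors.
* No spatial or temporal autocorrelation: simulated voxels are exchangeable
  and carry no anatomy.  The model quantifies variance contributions to
  map-level summary statistics; it does not predict where activations fall.

## Map statistics

Per subject and trial subset (all trials, odd trials = 1st/3rd/…, even
trials = the complement):

* **task map** — mean beta across the selected trials;
* **rt / confidence map** — two-sample pooled-variance Student *t* comparing
  betas on trials above vs. at-or-below the subset's median of the variable.
  Ties go to the low group; the median is recomputed within each subset so
  half-maps are self-contained.  A subset in which no trial exceeds the
  median raises a degenerate-split error rather than silently producing a
  one-group contrast.

Group maps are one-sample *t* across subjects with Benjamini–Hochberg FDR;
voxels with zero across-subject variance get an ±inf sentinel and a warning
rather than an exception.  Block aggregation averages betas and behavior
within each (run, block) and re-z-scores, after which all map operations
apply unchanged.

## Summary statistics

Top-X% voxel selection takes the ⌈X·V⌉ voxels with largest |statistic|
(capturing activations and deactivations), ties broken toward the lower
index.  Split-half reliability selects on each half in turn and averages the
two directed correlations; similarity selects on the subject's own all-trials
map and correlates against the unweighted mean of the remaining subjects.
Reported values are across-subject means ± SEM (SD/√n).

Useful closed forms (unit noise, T trials, n subjects) used as test oracles:

* task split-half reliability at 100% of voxels: S/(S + 2/T) with
  S = w_task_g² + w_task_s² (each half-map's noise mean has variance 2/T);
* group-only similarity: w_g²/√((w_g² + 1/T)(w_g² + 1/(T(n−1)))) — the
  held-out group map's noise shrinks by the factor n−1, which is why
  similarity can exceed reliability in group-dominated data.

## Consistency and overlap nulls

Sign consistency C[v] is the percent of subjects with activation ≥ 0, folded
about 50 (max(C, 100−C)); exact zeros are treated as out-of-mask and
excluded.  Top-fraction overlap is the percent of subjects selecting a voxel
in their top-X% set.  Because both statistics are maxima-prone over many
voxels, their null reference is the mean over iterations of the *maximum*
over voxels under independent maps.  Both statistics depend only on signs
and ranks, so the null distribution choice is immaterial; standard-normal
maps are used.  Exact companions: the folded count per voxel is
Binomial(n, ½)-distributed and the maximum over V independent voxels has
expectation computable from the CDF raised to V; the overlap null uses the
analogous Binomial(n, ⌈fV⌉/V) order-statistic expectation (an excellent,
slightly conservative approximation, since the fixed per-subject selection
total induces a weak negative dependence).  At 50 subjects the folded
consistency null is 80.0% for V = 5×10⁴ and 81.8% for V = 2×10⁵ — only
log-sensitive to the voxel count; the default whole-brain scale is
V = 200,000 (a typical 2-mm mask).

## Fitting

* Targets: the six 100%-fraction values (reliability and similarity ×
  task/RT/confidence).  The 10/25/50/75% curves are deliberately left out of
  the objective and serve as out-of-sample checks of the best fit.
* Common random numbers: one factor-map seed and one noise seed are fixed
  per fit, so the objective is a deterministic, smooth function of the
  weights.  This is implemented without rematerializing the
  subjects × trials × voxels array per evaluation: given fixed factors and
  noise, betas are linear in the weights, and every required map statistic
  depends on the noise only through cached per-voxel sufficient statistics
  (per-group noise means, sums of squares, and cross-products with the
  centered behavioral regressors).  The cached path is asserted in the test
  suite to agree with the naive simulate-then-map pipeline to floating-point
  reassociation error.
* Optimizer: bounded trust-region least squares (`scipy.optimize.least_squares`,
  method `trf`, finite-difference Jacobian with relative step 1e-3), box
  bounds [0, 3] per weight, restarted from 10 uniform-random points with the
  best restart reported.  A direction-set (Powell) search was evaluated
  first and needed thousands of evaluations to approach the optimum on this
  surface; with a deterministic smooth objective and only six residuals, the
  least-squares solver reaches machine-precision fits in ~100 evaluations,
  so it was adopted.  Restarting stops early once a restart attains an MSE
  below 1e-14, since best-of-n cannot improve on a machine-precision fit;
  on empirical (non-self-generated) targets this threshold is never reached
  and all restarts run.
* Information criteria: AIC = n·ln(SSE/n) + 2k and BIC = n·ln(SSE/n) +
  k·ln(n) with n = 6 summary values and k = 6 (full) or 3 (restricted)
  parameters, computed from the repetition-mean MSE in model comparison.
* Model comparison: each variant's best fit is re-evaluated on 25 fresh
  simulation seeds *shared across variants*, giving paired MSE samples for
  two-sided paired t-tests.

## Synthetic behavior

The generator emulates the study layout (6 runs × 16 blocks × 8 trials = 768
trials per subject) with log-normal RT (default median 1.0 s, σ_log = 0.4 —
a realistic unimodal, right-skewed RT distribution for an untimed two-choice
task) and confidence from a thresholded standard-normal latent (default
thresholds −1, 0, 1, giving rating probabilities ≈ 16/34/34/16%).  The model
consumes only z-scores, so these distributional choices affect realism, not
the fitted statistics.  Not emulated: stimulus difficulty, accuracy,
RT–confidence dependence on evidence, session effects, and any spatial
structure — so passing tests demonstrate the estimator's behavior under the
model's own assumptions, not robustness to real-data violations such as
autocorrelated voxels or non-Gaussian noise.

## Numerical choices and degenerate inputs

* Selected-voxel count is ⌈fraction·V⌉; correlation on zero-variance
  selections raises an undefined-correlation error.
* Median-split ties go to "low"; confidence is discrete, so heavy ties can
  make a subset's split degenerate — this raises rather than guesses.
* All randomness flows from integer seeds; noise streams are keyed by
  (seed, subject) so per-subject chunking is bit-identical to whole-array
  generation, and child seeds are derived via `SeedSequence` and kept below
  2³¹.
* Sufficient statistics are stored in float64; engine-vs-naive agreement is
  asserted at rtol 1e-8.

## Problem sizes in the test suite

Unit tests run at toy scale (≤ 50 × 768 × 300).  The end-to-end suite uses
the protocol's cohort shape with reduced voxel counts where the statistics
are voxel-count-insensitive: parameter recovery and model comparison at
V = 2,000 (map correlations stabilize well below 10,000 voxels), closed-form
oracles at V = 10,000, and the consistency null at the full V = 200,000 with
100 iterations (the maximum's mean has negligible Monte-Carlo error there).

## Known limitations

* Group-level fitting only: one weight per factor for the whole cohort; no
  hierarchical per-subject weights.
* The pooled-variance t assumes equal group variances; with strongly
  RT-modulated signal the high/low groups can differ in variance.
* The overlap null's analytic companion ignores the fixed-total dependence
  across voxels (negligible at whole-brain V, visible at very small V).
* Reported weights are conditional on w_noise = 1; only ratios and
  proportions are scale-free.
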