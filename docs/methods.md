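# Methods

## Generative model for the simulation study

Each simulated unit has a confounder `Z_i ~ U(0,1)`, a binary treatment,
and an ordinal outcome on J = 5 categories. Treatment is assigned with
probability `τ_i = Z_i` (scenario 1) or `τ_i = Z_i²` (scenario 2); the
marginal treated fraction is therefore 1/2 and 1/3 respectively. The
outcome follows a proportional-odds cumulative logit whose linear
predictor is `βX_i + γZ_i` (scenario 1) or `βX_i + γZ_i²` (scenario 2).

**Sign convention.** We write `logit P(Y ≤ j) = α_j − (βX + γZ)`: the
linear predictor enters with a minus sign, as in the standard
proportional-odds parameterisation, so positive β and γ shift mass toward
higher categories. Under this convention higher Z goes with both more
treatment and higher outcomes, so the unadjusted treatment estimate is
biased upward — the configuration the whole study is about. Any source
using the opposite (plus) convention differs only by the sign of the
slopes.

**Thresholds.** `α_j = logit(p_1 + … + p_j)` from the baseline category
probabilities `(0.15, 0.20, 0.30, 0.20, 0.15)`; at zero linear predictor
the outcome reproduces those probabilities exactly, and the symmetric
baseline gives antisymmetric thresholds `(−1.7346, −0.6190, 0.6190,
1.7346)`.

**Category sampling** is inverse-CDF with a single uniform per unit.
Each design cell uses one root seed with separate sub-streams for Z, X
and Y; reproducibility holds for a fixed `(design, seed)` pair, but
prefix stability across different n is deliberately not promised.

## Weighted cumulative-logit estimation

The model is fit by maximising the weighted multinomial log-likelihood
`Σ w_i log P(Y_i = y_i | x_i)` with L-BFGS-B and an analytic gradient.
Threshold monotonicity is enforced by construction: `α_1` is free and the
remaining thresholds are parameterised through log-increments, so the
optimisation is smooth and unconstrained. Starting values are the
empirical weighted cumulative logits with zero slopes. Point estimates
are invariant to rescaling all weights by a constant.

The covariance is the inverse observed information at the optimum,
obtained by central finite differences of the analytic gradient in the
direct `(α, b)` parameterisation and computed lazily (the Monte-Carlo
loops only need point estimates). This treats weights as fixed: Wald CIs
are only reported for fits whose weights are known (unit or sampling
weights), while propensity-weighted fits get percentile-bootstrap CIs
that re-run the whole pipeline — propensity fit, weight construction,
outcome regression — on every resample (rows are resampled uniformly;
sampling weights travel with their rows). The percentile flavour was
chosen for transparency; fewer than ~150 replicates visibly truncates the
heavy upper tail of ATT-weighted estimates, so 500 is the production
default. Failed replicates are dropped and counted; more than 10%
failures is an error, not a silent degradation.

Degenerate inputs: outcomes with unobserved intermediate categories are
collapsed onto the observed levels with a warning; a single observed
category is an error; non-convergence is flagged on the results object
and propagated as a replicate failure inside the Monte-Carlo loop.

## Propensity model and weights

Treatment probabilities are estimated with gradient-boosted
classification trees (logistic deviance, depth 3, no row subsampling).
Depth 3 lets the model learn the quadratic assignment of scenario 2
without being told; the binned-histogram implementation is used for
speed, with continuous covariates pre-quantised to ≤255 unweighted
quantile midpoints when sampling weights enter the fit (numerically
equivalent to the binner's own discretisation, and orders of magnitude
faster than its weighted-percentile path).

**Balance-criterion stopping.** By default the boosting iteration that is
actually used is the one minimising the mean absolute weighted SMD over
the covariates (`stop_method="smd.mean"`), scanning staged predictions up
to the configured tree count; this is the convention of balance-tuned
propensity boosting. A `"fixed"` mode that always uses all trees is
available. The distinction matters: with a fixed count the trees
partially memorise the realised assignments, which shrinks the weights
toward 1 and under-corrects confounding.

Weights: stabilized IPTW `WS_i = p_x/π̂_i` (treated) and
`(1−p_x)/(1−π̂_i)` (controls) for the average-treatment-effect analyses;
ATT weights (treated ≡ 1, controls `π̂/(1−π̂)`) for the applied survey
analysis, whose question is the effect of vaccination on the vaccinated.
Probability clipping is off by default and available as a config option.
In the applied pipeline the regression weight is the product of the
sampling weight and the ATT weight, and "before-weighting" balance is
computed on the sampling-weighted sample.

Balance diagnostics: SMD per covariate (per-level, max-summarised for
categoricals; weighted means and variances in the weighted phase), Kish
effective sample size `(Σw)²/Σw²`, and a tidy love-plot table sorted by
unweighted SMD.

## The Monte-Carlo study

Methods A–D as in the README table; K replicates per design cell over
the grid n ∈ {200, 500, 1000, 2000}, β ∈ {0.25, 0.5, 1.0},
γ ∈ {1, 2}, both scenarios, with the propensity model refit inside every
replicate (200 trees maximum, learning rate 0.1). Replicate seeds derive
deterministically from the root seed keyed by (cell, replicate), so
reports are reproducible regardless of execution order. `ARebias` is the
mean relative error with standard error `SD/√K`; failed fits are dropped
and counted. Rendered tables flag `|ARebias| ≥ 5%`.

## The synthetic survey

`generate_survey` emulates the structure of a national vaccination
survey: ~88.7% vaccinated, four sociodemographic categoricals, infection
history, chronic disease, and seven standardized psychometric factor
scores, plus lognormal sampling weights (σ = 0.35, mean 1) and three
7-point adherence outcomes. Confounding is specified as signed SMD
targets per covariate (defaults follow the magnitudes typical of
vaccine-hesitancy surveys, up to ≈0.85 for trust in health information).
Vaccination is assigned by a logistic model on the standardized covariate
scores; a damped fixed-point calibration on a fixed internal population
sample (n = 20 000) sets the coefficients so the induced SMDs hit their
targets within 0.005 and the intercept so the prevalence hits its target.
Unreachable targets (e.g. an SMD of 5 for a binary covariate) raise a
calibration error.

Outcomes are cumulative-logit draws whose linear predictor combines a
configurable true treatment log-OR (default 0, i.e. no real effect) with
covariate effects proportional to the SMD targets. The per-outcome
proportionality constants (0.12, 0.17, 0.26) are calibrated so that the
naive sampling-weighted odds ratios at true OR = 1 are ≈1.45, 1.65 and
2.2 — the range typical of unadjusted vaccination–adherence associations
— making the generator a realistic test bed for the adjustment methods.

What the generator does **not** emulate: item-level response behaviour
behind the factor scores, within-household or regional clustering,
informative missingness, and any dependence structure among covariates
beyond that induced by the assignment model. Passing tests therefore
demonstrate that the estimators remove the kind of confounding the
generator encodes, not that they would remove every bias present in a
real survey.

## Problem sizes used by the test suite

The acceptance-grade Monte-Carlo checks run at the published design
points with K = 1000 replicates at n = 2000. Supporting property checks
use smaller replicate counts chosen as the package's own trade-off
between statistical resolution and turnaround: the full-grid
sign-of-bias check at K = 30 (the unadjusted bias is ≥30% of β in every
cell, so 30 replicates resolve its sign beyond doubt), MSE-ordering
checks at K = 150–300, and the applied-pipeline null-recovery experiment
at 100 repetitions of an n = 850 survey restricted to the seven
factor-score confounders with 120 bootstrap replicates (50 trees,
learning rate 0.18).

## Known limitations

- **PS-only adjustment (method C) retains residual bias.** In-sample
  boosted propensities under-correct confounding even with
  balance-criterion stopping: part of the fitted signal is memorised
  assignment noise, which drags the weighted covariate distributions
  toward the observed ones without removing true imbalance. In scenario 1
  at n = 2000 this leaves method C with a relative bias an order of
  magnitude above method B's, and in the survey setting the C point
  estimate stays biased away from the null while its bootstrap CI
  re-centres on the biased value, costing coverage. Covariate adjustment
  on top of the weights (method D) absorbs this residual confounding,
  which is the practical argument for the combined estimator.
  Cross-fitting the propensity model removes the memorisation bias but
  explodes weight variance at 11% controls, and is not implemented.
- **ATT estimates under extreme prevalence are noisy.** With ~89%
  treated, the effective control count after ATT weighting collapses
  (Kish ESS of a few dozen), so single-run effect estimates scatter
  widely; unbiasedness holds on average and the bootstrap CIs reflect
  the width honestly.
- Proportional odds is assumed, not tested; non-proportional and probit
  variants, PS matching/stratification, and doubly-robust estimators are
  out of scope.
- The Wald covariance ignores weight-estimation uncertainty by design;
  use the bootstrap CIs for any weighted analysis.
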