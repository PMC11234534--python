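# Methods

## The design problem

A logistic prediction model π = expit(β₀ + βᵀx) is to be developed by
maximum likelihood on n participants. Before data collection the designer
can usually anticipate three quantities: the outcome prevalence φ, the
model's discrimination (c-statistic c), and the number of predictor
parameters p. The package treats the *expected* validation performance of
the not-yet-fitted model as a function of n and solves for the n that meets
a target — either a target expected calibration slope S (α₁ in the
recalibration model logit π = α₀ + α₁ η̂ fitted to validation data) or a
target expected MAPE m = E|π̂ − π|.

## Calibrating a population to (φ, c)

Everything rests on a working assumption: across the population the true
linear predictor η is normal, η ~ N(μ, σ²). Then

- prevalence: φ(μ, σ) = E[expit(η)], a 1-D Gaussian integral;
- c-statistic of the true model:
  c(μ, σ) = E[expit(η₁)(1 − expit(η₀)) 1{η₁ > η₀}] / (φ(1 − φ)) with
  η₀, η₁ iid N(μ, σ²).

`solve_lp_distribution` inverts (φ, c) ↦ (μ, σ) by nesting two monotone
1-D root-finds: for any σ, μ is matched to φ by bisection (the prevalence
is strictly increasing in μ); the induced c is then strictly increasing in
σ, so an outer bracketing search on σ closes the system. Both residuals are
driven below 1e-6. This nested scheme was chosen over a 2-D Newton solver
because each sub-problem is monotone, making convergence unconditional.

1-D integrals use 128-node Gauss–Hermite quadrature (the integrands are
smooth functions against a normal weight). The concordance double integral
is evaluated as nested 1-D integrals on a 4097-point grid of the
standardised predictor over [−8.5, 8.5] (inner cumulative Simpson, outer
Simpson); the truncation and quadrature errors are orders of magnitude
below the solver tolerance.

Concrete coefficients follow from the predictor structure. With zero-mean
continuous predictors of correlation R and relative strengths γ, β = f·γ
with f = σ / √(γᵀRγ) and β₀ = μ. Binary predictors are *not* standardised:
the variance equation uses Bernoulli variances and β₀ absorbs the mean
shift f·γᵀE[x]. The default 12-predictor study design has 5 true
predictors with strengths (0.4, 0.2, 0.2, 0.1, 0.1) and 7 noise
predictors, correlations 0.1 (true–true), 0.05 (noise–noise), 0 (cross);
the worked-example design uses equal strengths and independence. For a
given (φ, c, σ) the expected CS and MAPE at a given n are insensitive to
which structure generated the predictors, which is why the search defaults
to independent equal-strength predictors.

## Cox–Snell R² from (φ, c)

The calibration formula needs R²_CS = 1 − exp(−LR/n). Its population
version is 1 − exp(−2(ℓ̄_model − ℓ̄_null)) with ℓ̄ the expected
per-observation log-likelihood. Two derivations are provided:

- `method="binormal"` (default): the standard approximation assumes η is
  normal with unit variance *within* events and non-events, so the mean
  separation is δ = √2·Φ⁻¹(c) and the true risk is exactly
  logistic-linear, p(η) = expit(logit φ − δ²/2 + δη). The expectation is
  taken over the two-component normal mixture.
- `method="marginal"`: reuses the marginal-normal calibration above.

The two agree within a few thousandths over the study grid, and both agree
with the large-sample simulated estimate `r2cs_from_large_sample`
(1 − exp(−LR/N) after one MLE fit to N = 10⁶ simulated observations)
within 0.01. The binormal version is the default because it is the
approximation in standard use for this purpose. Note the closed-form n is
very sensitive to R² when R² is small (n ∝ 1/R² to first order), so sample
sizes derived from a simulated R² at weak model strength inherit a
Monte-Carlo error of a few percent even at N = 10⁶.

## The simulation engine

`evaluate_performance(spec, n, n_sim, n_val, seed)` repeats n_sim times:
simulate a development sample of size n, fit the logistic model by MLE
(statsmodels), compute η̂ and π̂ on a fresh validation sample of size
n_val, and record CS (recalibration slope), c-statistic (midrank Wilcoxon
form, identical to the all-pairs estimator with ties scored ½) and MAPE.
Summaries carry Monte-Carlo standard errors (SD/√n_sim), the RMSD of the
CS from 1, and the stability probabilities P(CS < 0.8), P(CS < 0.9) and
P(|ĉ − c| ≤ 0.02).

Defaults n_sim = 1000 and n_val = 25 000 keep the MCSE of the mean CS
around 0.0025 at the sizes relevant to a target S = 0.9; a
study-replication mode (n_sim = 2000, n_val = 100 000) is available by
argument. Development fits that fail to converge or show quasi-separation
(|η̂| > 30 on the training data) are discarded and redrawn from a fresh
substream — the estimand is the performance of models *successfully fitted
by MLE* — with a warning if exclusions exceed 1% of replicates.

Random streams: replicate i derives its development and validation streams
from SeedSequence entropy (seed, i, ·). Predictor and outcome draws are
filled row-wise from separate child streams, so a development sample of
size n₁ is exactly the first n₁ rows of the sample of size n₂ > n₁ from
the same replicate. Evaluations at different n therefore share common
random numbers, which makes the mean-performance curve smooth in n and is
what allows a stochastic bisection to work with moderate n_sim.

## The search

`find_n_for_cs` / `find_n_for_mape` bracket the solution starting from the
corresponding closed-form value (initial bracket [n/2, 4n], expanded
geometrically if needed), then bisect on a grid of 10 using the common
random numbers above; the mean CS is increasing and the mean MAPE
decreasing in n. Stopping: |mean − target| ≤ tol (defaults tol_CS = 0.005,
tol_m = 0.002·m) or bracket width ≤ 10, followed by a secant interpolation
between the tightest bracketing evaluations and a confirmatory evaluation
at the returned n (rounded up to the nearest 10). If an interior
evaluation falls outside the bracketing values by more than 5·tol — noise
exceeding what bisection tolerates — n_sim is doubled once before failing
with the evaluation trace. A target so weak that it is met at the smallest
usable size (n·φ ≈ 2p) returns that bound with an explanatory message.

The returned n inherits two sources of fuzz: the grid of 10 and the
Monte-Carlo error of the mean metric divided by its local slope in n
(roughly ±30–60 participants for the worked example at n_sim = 1000).
These are reported via the evaluation trace and the achieved metric with
its MCSE.

## Survival extension

For time-to-event outcomes, T | η ~ Exponential(h₀·e^η) (constant baseline
hazard h₀, default 0.1), administratively censored at a time point solved
so that a prespecified proportion of observations is uncensored (the
marginal event probability E_η[1 − exp(−h₀e^η t)] is computed by
quadrature and inverted by bisection). Model strength is the censoring-free
concordance: a pair with predictors (a, b) is concordant with probability
expit(|a − b|), so c = E[expit(|D|)], D ~ N(0, 2σ²), a 1-D integral
inverted for σ. Development fits use the Cox partial likelihood
(lifelines); performance is the survival calibration slope (coefficient of
η̂ in a Cox model on validation data) and Harrell's c-index. The survival
R²_CS (1 − exp(−LR/N) from the partial-likelihood ratio) depends strongly
on the censoring fraction, which is what drives the calibration formula's
deterioration when few observations are censored at high model strength.

## What the generator does and does not emulate

The generator reproduces the joint behaviour of MLE-fitted logistic (or
Cox) models under a correctly specified model with normal (or Bernoulli)
predictors and no missing data, no measurement error and no variable
selection. Passing tests therefore speak to sample-size requirements under
those idealised conditions; they do not certify performance under model
misspecification, informative censoring, or data-driven predictor
selection, all of which typically *increase* the required n.

## Problem sizes used in the checks

The packaged checks run the worked example at n_sim = 1000 replicates with
n_val = 25 000, the events-per-variable searches at n_sim = 500, and
large-sample calibration checks at N = 10⁶; these sizes put the
Monte-Carlo error comfortably inside the tolerances asserted while keeping
a full run in the minutes range on a single CPU. The survival ordering
checks use deliberately small replicate counts (tens) because only a
direction, not a magnitude, is asserted.
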