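# Methods

`curemap` implements a survival-score pipeline for registry-style cohorts of
the kind kept for end-stage kidney disease (ESKD): every subject has a
follow-up time, a death indicator, categorical demographic/comorbidity
covariates plus one continuous comorbidity index, a county nested in a
region, and optionally out-of-model clinical measurements. This note records
the models, conventions and numerical choices the package uses, and what its
synthetic data can and cannot say about real registries.

## The mixture cure model

Registry populations mix two very different groups — for ESKD, long-term
transplant recipients versus dialysis patients — so a single
proportional-hazards model fits poorly. The mixture cure model (MCM) writes
the population survival for covariate vectors (x, z) as

    S(t; x, z) = pi(z) * S0(t)^exp(beta' x) + 1 - pi(z)

with

* **incidence**: `pi(z) = expit(b' z)`, the probability of being *uncured*
  (subject to the event); `1 - pi(z)` is the cure fraction and the asymptote
  of the survival curve;
* **latency**: `S(t; x) = S0(t)^exp(beta' x)`, a semiparametric
  proportional-hazards model for the uncured, with a nonparametric baseline
  `S0`.

### EM estimation

The fit alternates:

* **E-step.** Subjects with an observed event are uncured with certainty
  (posterior weight 1). For a subject censored at t the posterior weight is
  `w = pi * S_u(t) / (pi * S_u(t) + 1 - pi)`.
* **M-step.** `b` is refit by weighted maximum-likelihood logistic
  regression of `w` on z (a fractional-response GLM); `beta` by a Cox
  partial likelihood with case weights `w` entering both the event terms
  and the risk sets, with Breslow tie handling; the baseline cumulative
  hazard is the Breslow estimator under the same weights.

A **zero-tail constraint** sets `S0(t) = 0` beyond the largest event time.
Without a tail constraint the cure fraction is not identifiable from
censored data; the zero tail is the standard choice and makes subjects
censored past the last event cured with posterior certainty.

Numerical choices:

* Initialization: `b` from a logistic regression of the raw event indicator
  on z; `beta` from a plain Cox fit to everyone. Both are deterministic.
* Convergence: damped relative change `|delta| / (1 + |old|) < 1e-6` for
  every coefficient, at most 500 EM iterations. The damping avoids division
  blow-ups for near-zero coefficients.
* The observed-data log-likelihood (using the Breslow hazard increments for
  events and the mixture survival for censored subjects) is recorded every
  iteration; a decrease beyond `1e-8 * (1 + |loglik|)` flags the fit and
  emits a warning. In practice the trace is monotone.
* The Cox inner fitter is Newton–Raphson with step-halving (at most 100
  iterations, relative log-likelihood change `< 1e-9` or gradient sup-norm
  `< 1e-6`), linear predictors centred before exponentiation, and a
  diverging-coefficient warning for |beta| > 50 (separation).
* `pi` is clipped to `[1e-12, 1 - 1e-12]` inside the E-step.

Standard errors are nonparametric subject-level bootstrap (default 100
resamples, configurable; the pipeline demo uses 30 to keep the run short).
Resamples that fail to converge are dropped and counted; more than 50%
failures aborts. Wald z-values are estimate/SE per coefficient, computed
separately for the incidence and latency parts.

### Degenerate mode

`mcm_fit(..., force_uncured=True)` pins `pi = 1` so every posterior weight
is 1 and the latency fit collapses to a plain Cox fit — used as an internal
consistency check. Fitting data in which everyone is in fact uncured gives
the same result only approximately, because administratively censored
survivors past the last event time receive weight 0 under the zero tail.

## Concordance and model comparison

Risks live on the linear-predictor scale: higher risk means shorter
expected survival. A pair of subjects is **comparable** iff their observed
times differ and the subject with the smaller time had the event; a
censored time certifies survival only beyond itself, so a pair whose
earlier time is censored is not ordered. Pairs with exactly equal observed
times — including two tied event times — are excluded (the tie-splitting
formula has no tied-time category; this convention is isolated in
`_pair_counts` and easy to revisit). The estimate splits risk ties:

    C = (c + t_y/2) / (c + d + t_y)

Counting is exact (chunked O(n^2)), and per-subject pair contributions are
retained so the **ordinary jackknife** needs no recomputation: the
leave-one-out concordance removes subject i's pairs from the counts. The
variance is `(n-1)/n * sum_i (theta_(i) - theta_bar)^2`. For moderate to
large samples this agrees with the weight-perturbation (infinitesimal)
jackknife, which is why the simpler estimator is used.

**Monte-Carlo cross-validation** refits the model on random train/test
splits (default 100 splits, 80/20) stratified by event status, so every
split reproduces the full event proportion to rounding. The reported
standard error is the sample standard deviation of the test-set
concordances divided by sqrt(splits), with a normal-based confidence
interval.

The **entire-vs-region comparison** follows the surrogate strategy: Cox
models stand in for the MCM (which is expensive to refit hundreds of times
inside MCCV), the entire-data model includes region dummy covariates, and
the per-region models exclude them. Each region is scored two ways — the
entire-data model evaluated on the region's subjects, and a region-only
model — with jackknife and MCCV uncertainty; the 'entire' row is the same
model under both schemes by construction.

## The seven survival scores

For a profile (x, z): survival probabilities at 2, 5, 10, and 15 years, and
the times at which survival first reaches 75%, 50%, and 25%. The horizons
suit a cohort whose events concentrate early within a ~21-year follow-up.
Quantile times invert the right-continuous step curve as the *earliest knot
time with S(t) <= q* (no interpolation between knots). When the cure
fraction exceeds `1 - q` the curve never reaches q; the score is clamped at
the maximum follow-up time (default 21.5 years) and flagged rather than
reported missing. The latency/incidence decomposition returns
`S(t; x)` and `pi(z)` separately and satisfies
`S_total = pi * S_latency + (1 - pi)` to machine precision. A nonparametric
overlay reads the same seven scores off a Kaplan–Meier curve for
cohort-level figures.

## County summarization

Three schemes summarize scores across counties:

1. **Univariate mode** — per covariate independently, the most frequent
   level in the county (continuous covariates rounded to their native
   resolution first); the seven scores are then computed for that profile.
   Ties break deterministically to the earliest level in schema order and
   are logged.
2. **Multivariate mode** — the strictly most frequent *combination* of the
   most important categorical predictors; if no strict maximizer exists the
   least-important variable is dropped and the search retried (fallback
   depth recorded). Remaining covariates are filled univariately. The
   continuous comorbidity index is excluded from the joint mode because a
   continuous variable almost never admits one.
3. **Multiple mode** — scores are computed per individual first, then a
   Gaussian-kernel density of each score within the county is scanned for
   its two tallest peaks. Bandwidth is Silverman's rule
   `h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)` with the sample sd (ddof = 1)
   and type-7 quantiles — the dialect of R's default density estimator —
   falling back to the sd when the IQR is zero. The density is evaluated on
   a 512-point grid over `[min - 3h, max + 3h]`; peaks are discrete
   sign-change maxima ordered by height. The second mode must exceed the
   valley separating it from the first by 5% of the peak density, which
   suppresses grid-level wiggle; otherwise it is reported missing. Peak
   order is by height (not location): with right-skewed score
   distributions the second, shorter peak typically sits at higher
   survivability.

**Variable importance** sums |z| over the two model parts per covariate
level (each level has one incidence and one latency coefficient) and sorts
descending. The cutoff is the largest gap between consecutive sorted values
— the clearest break in the empirical CDF — or a fixed top-k override; the
pipeline default is top 5, mirroring common practice of carrying a handful
of leading predictors into downstream summaries.

**Suppression.** Any county summary derived from 1–10 subjects may not be
reported. Such counties have *every* reported field replaced by a summary
of their adjacent non-suppressed counties: mode for categorical fields,
mean for numeric fields, with an imputed flag. A suppressed county with no
eligible direct neighbor expands once to neighbors-of-neighbors; if that
also fails it is flagged unresolved and left empty. Donor counties are
iterated in sorted order so floating-point reductions are identical across
runs. Counties with zero subjects are simply absent.

**Representative individuals.** To characterize a mode, the county resident
whose chosen score is nearest the mode value is reported (ties to the
lowest id), along with their categorical profile — e.g. transplant status,
which typically separates the two modes.

**Clinical validation.** Out-of-model clinical measurements are correlated
with each score after removing values beyond the 1.5×IQR fence, at the
individual level and at the county level (means and medians). Small-county
noise attenuates county-level correlations relative to the individual
level.

## The synthetic cohort generator

The generator is the testbed standing in for access-restricted registry
data. It draws, per subject: covariates from a schema of several
categoricals (transplant status, race, ethnicity, primary disease) plus a
right-skewed nonnegative gamma comorbidity index; cure status
`Bernoulli(pi(z))` from a logistic model with known b; event times for the
uncured from a Weibull proportional-hazards model with known beta; and
censoring as the minimum of an exponential time (rate 0.02/year,
covariate-independent) and an administrative boundary at 21.5 years.
Geography is a grid of counties (rows = counties per region, columns =
regions) with rook adjacency and contiguous column-block regions; county
sizes follow a lognormal weight (sigma = 1.6) apportioned by largest
remainder, which yields the 1–10-person and empty counties needed to
exercise suppression. An optional per-region scaling of the latency linear
predictor plants regional heterogeneity for the model-comparison tests. A
clinical analog is attached as an affine function of the standardized
latency linear predictor plus Gaussian noise, so its correlation with the
linear predictor equals the configured link strength exactly in
population; the default link of -0.47 makes the analog rise with
survivability, the direction reported for serum creatinine in registry
validation studies.

Default true coefficients echo the sign pattern seen in ESKD registries
(transplant and Hispanic protective in both parts, Black race protective in
latency, hypertension/glomerulonephritis lowering the odds of being
uncured) with every magnitude at most 1. The Weibull baseline
(shape 1.4, scale 3.5) makes the uncured latency distribution essentially
exhausted before the administrative boundary — baseline survival at 21.5
years is ~1e-5 — which matches a cohort whose events concentrate early and
gives a clean Kaplan–Meier plateau at the cure fraction; a heavier latency
tail would deliberately confound cure with slow latency and is available by
configuration.

What the generator does **not** emulate: real county adjacency or
population distributions (the grid is a synthetic stand-in), within-county
covariate clustering beyond region effects, covariate-dependent censoring
(the exponential+administrative mechanism is an assumption; registries do
not publish their censoring law), and measurement error in covariates.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline mechanics under a known truth, not transportability of any fitted
coefficients to real data.

## Problem sizes and runtime choices

The test suite and `scripts/acceptance.py` fit recovery cohorts at
n = 5,000 over 10 seeds; the suite runs the end-to-end determinism check at
n = 1,500 with trimmed bootstrap/MCCV counts and keeps single fixtures at
n <= 2,000. The acceptance script additionally runs the full demo pipeline
(n = 5,000, 100 counties, 30 bootstrap resamples, 100 MCCV splits) twice to
verify byte-identical reproduction; the demo completes in about a minute on
one CPU. These sizes are the package's own calibration: large enough that
Monte-Carlo error is well inside the asserted tolerances, small enough to
iterate quickly.

## Known limitations

* Only Breslow tie handling; no Efron/exact ties, time-varying covariates
  or stratified baselines.
* The concordance comparability convention for exactly tied times is a
  documented choice, not a registry standard.
* The ECDF-gap importance cutoff is a heuristic; the pipeline uses a fixed
  top-5 override for stability on small synthetic fits.
* County tables export raw score values; the log/logit map transforms used
  for choropleth display are left to the caller.
* Bootstrap SEs assume enough events per resample; very small regions can
  push resample failure rates up, which is surfaced rather than hidden.
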