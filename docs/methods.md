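# Methods

`gutsgof` implements, as one tested pipeline, the comparison of quantitative
goodness-of-fit (GoF) metrics for GUTS survival-model fits with the visual
assessment of those fits by human evaluators: forward modeling and Bayesian
calibration of GUTS-RED, the GoF metric suite and its combination rules, the
assembly of time-series and dose-response fit images, a synthetic survey of
evaluator scores, and the ordinal-regression / acceptance-threshold
inference chain.  Because the survey responses and toxicity datasets behind
the original analysis are not publicly deposited, every stage is validated
by parameter recovery on synthetic data with known truth rather than by
numerical reproduction of survey-dependent estimates.

## GUTS-RED forward model

Scaled damage follows first-order kinetics driven by the external
concentration, `dD/dt = kd (C_w(t) − D)` with `D(0) = 0`.  Exposure
profiles are piecewise constant or piecewise linear; on each segment the
solution is exponential-affine, `D(τ) = A + Bτ + G e^(−kd τ)`, so damage is
evaluated analytically and is continuous across segment boundaries.  After
the last profile point the last concentration is held.

* **Stochastic death (SD).**
  `S(t) = exp(−hb·t − b ∫₀ᵗ max(0, D(τ) − z) dτ)`.  The hazard integral is
  computed exactly per segment: each segment is split at its (at most one)
  interior damage extremum, threshold crossings are solved in closed form on
  constant segments and by bracketed Brent root finding at machine precision
  on linear ones, and the integral of `D − z` over the supra-threshold part
  is analytic.  No fixed-step quadrature is involved, so there is no
  tolerance to tune; the only numerical parameter is the root-finder
  precision (`xtol = 1e−14`).
* **Individual tolerance (IT).**
  `S(t) = [1 − F(max_{τ≤t} D(τ))]·e^(−hb·t)` with a log-logistic threshold
  distribution `F(x) = 1/(1 + (x/mw)^(−β))`, `F(0) = 0`.  The running
  maximum of damage is taken over the per-segment analytic extrema, so the
  survival curve is exactly non-increasing.

Parameters and units: `hb` background hazard (1/d), `kd` dominant rate
constant (1/d), `z` threshold and `mw` median threshold (exposure units),
`b` killing rate (1/(exposure unit·d)), `β` dimensionless shape.  Time is
days throughout; concentration units are arbitrary but must be consistent.

Survivor counts are sampled forward by conditional binomials on consecutive
observation times, so the marginal count at time `t` is
`Binomial(n0, S(t))`.

## Calibration

The likelihood is the conditional-binomial death chain,
`∏_t B(y_t; y_{t−1}, S(t)/S(t−1))` per treatment, equivalent to the
multinomial distribution of deaths per interval.  Conditional ratios are
floored at `1e−12` before the log; an exact-zero predicted survival with
observed survivors yields `−∞` rather than an exception.

Priors are independent log-uniform on `kd`, `b` (or `β`), `z` (or `mw`),
and uniform on `hb ∈ [0, 0.1]/d`.  The threshold range defaults to
`[0.01 × min positive tested concentration, 10 × max tested
concentration]`.  The `kd` range is data-driven by default,
`[0.05/t_end, 3/Δt_min]` with `Δt_min` the shortest observation interval:
kinetics faster than ~95% equilibration within one observation interval, or
slower than a few percent of equilibration over the whole test, leave no
signature in the counts, and including decades of such unidentifiable rates
only skews the posterior along the well-known `kd`–`z`–`b` ridge.  Both
ranges are configurable.

Sampling uses an adaptive random-walk Metropolis (4 chains, Haario-style
proposal adaptation during burn-in only, frozen afterwards), started from a
coarse 300-point prior search.  Defaults: 3000 burn-in steps and 500
retained draws per chain (2000 draws total).  The long burn-in is
deliberate: with shorter adaptation the split R-hat on realistic datasets
was 1.1–1.9.  Convergence is summarized by split R-hat and effective sample
size (arviz); R-hat > 1.05 sets a flag but is not fatal.  All randomness
flows through one integer seed; identical seed, data and settings give
bit-identical draws.

Posterior predictive summaries report, per treatment and time, the median
of `n0·S(t)` (the plotted median curve) and a 95% interval that by default
binomially resamples each draw's count — an interval for the observable
integer count, which is what the PPC metric needs.  The resampling can be
switched off to get an interval for the expected count only.

## GoF metrics

For paired observed/predicted survivor counts over all treatments and
times:

* `NRMSE = 100 · RMSE / mean(y_obs)` (percent),
* `PPC` = percentage of observations inside their 95% predictive interval
  (closed interval — boundary values count as inside),
* `SPPE_k = 100 · (y_end_obs − y_end_pred)/n0` per treatment;
  `SPPE_min = min(min_k SPPE_k, 0)`, `SPPE_max = max(max_k SPPE_k, 0)` —
  values with the wrong sign are clipped to 0 because they represent no
  error in that direction,
* Nagelkerke pseudo-R² at end-of-test counts,
  `R² = [1 − (L0/LM)^(2/n)] / [1 − L0^(2/n)]`, with the null model using
  the pooled survival fraction across treatments.  The likelihoods are
  products of binomial probabilities over treatments, evaluated in log
  space.

Rows at `t = 0`, where the prediction is exactly `n0`, are excluded from
NRMSE, PPC and the observed mean: they carry no information and would
deflate NRMSE and inflate PPC.  This is a convention choice; the exclusion
can be disabled when building the paired series.

Scaling to [0, 1] (1 = best) is linear on the 0–100% range: `ppc/100`,
`1 − nrmse/100`, `1 − |sppe|/100`, all clamped to [0, 1]; pseudo-R² clamps
negatives to 0.  The combined **average GoF** and **minimum GoF** are the
mean and minimum of the scaled NRMSE, PPC, SPPE_min and SPPE_max.  Under
this linear scaling a minimum-GoF cut of 0.54 corresponds to NRMSE ≲ 46%,
PPC ≳ 54% and |SPPE| ≲ 46%, which is the sense in which the minimum-GoF
threshold can be compared with the regulatory suggestion NRMSE ≤ 50% and
PPC ≥ 50%.

Fit selection for the survey drops fits without a ≥ 70% end-of-test effect
in at least one treatment (inclusive boundary) and experiments with a
single treatment, then subsamples to approximately equal counts per
average-GoF bin (5 equal-width bins by default, seeded).

## Fit images

Time-series images contain one panel per treatment: observed survival
proportions with 95% Wilson score intervals, the posterior-median predicted
survival curve, and the 95% band.  Dose-response images contain one panel
per experiment: end-of-test survival against each treatment's maximum
concentration, and a predicted curve obtained by multiplicatively scaling
the panel's reference exposure profile across a concentration grid and
evaluating posterior median and 95% band of end-of-experiment survival.
Profile scaling is the minimal-assumption construction for a
concentration–response curve under a shared exposure pattern; controls are
placed at a pseudo-position on the log axis.  All panels carry equal-size
layout metadata, and payloads serialize to JSON.

## Synthetic survey

The generator emulates an online survey: every evaluator scores 20 images
in a fixed block order (5 calibration time series, 5 calibration DRCs, 5
validation time series, 5 validation DRCs), drawn randomly without
replacement within blocks.  The default evaluator pool reproduces the
surveyed population: 64 evaluators, affiliations academia/authority/CRO/
industry/other/not-specified with proportions 15/5/13/24/6/1, and five
experience levels with proportions 14/16/12/14/8 (most to least
experienced).

Scores follow a latent cumulative model: latent
`η = β_g·g + β_v·v + affiliation + β_e·(e−3) + β_gv·g·v + β_ge·g·(e−3) + u`,
with `g` the combined GoF, `v` the validation indicator, `e` experience
1–5, and `u ~ Normal(0, σ)` one intercept per evaluator; the score is the
category of `η + ε` under the link noise (probit default).  Default truth:
cutpoints (−5.2, −4.45, −3.7, −2.7, −1.7), `β_g = −5`, `β_v = 0.15`,
`β_e = −0.05`, `β_gv = −0.2`, `β_ge = −0.4`, affiliation contrasts 0,
`σ = 0.5`.  The geometry puts 50% acceptance (P(score ≤ 3) = 0.5) at
`g = 0.74` for a reference evaluator, and the negative GoF × experience
coefficient makes experienced evaluators score more extremely — the
qualitative pattern the inference stage must recover; the magnitudes are
free configuration, not claimed ground truth.

Rejection reasons attach only to scores 4–6.  For time-series images the
end-of-test vs time-course group is Bernoulli with logit linear in the four
scaled metrics (default coefficients −0.954 intercept, −0.743 SPPE_min,
−0.654 SPPE_max, +1.397 NRMSE, +1.028 PPC — negative coefficients mean the
metric marks fits bad when they fail at the end of the test); the
one-panel/multiple-panel letter follows a 1:2 proportion.  DRC images draw
among the four DRC-specific reasons with fixed proportions.

The fit library behind the survey is synthetic: data are simulated from
known GUTS-RED-SD parameters and "predictions" come from the same
parameters perturbed on the log scale by a per-fit jitter swept from 0 to
1.1, with central binomial predictive intervals.  This spans the full GoF
range at negligible cost.  What it does **not** emulate: per-fit posterior
parameter uncertainty (intervals carry sampling error only), learning
effects over the 20-image sequence, and between-metric independence — as in
real fit collections, the five metrics of a library fit are strongly
correlated, which is why the rejection-reason recovery simulation draws
metrics independently instead.

## Inference

All ordinal models are Bayesian cumulative regressions with a latent-
variable link (probit default, matching a latent normal score; logit
available) and free cutpoints.  Priors: Normal(0, 2.5) on coefficients of
unit-variance-scaled columns, Normal(0, 10) on cutpoints with an ordered
(log-increment) transform, half-Normal(0, 2) on the random-intercept SD.
Affiliation is dummy-coded against academia; experience enters as a
centered integer score.

Estimation defaults to MAP plus a Laplace approximation (finite-difference
Hessian, eigenvalue-clipped), which at survey sample sizes (~1000+
observations) gives intervals indistinguishable from MCMC at a small
fraction of the cost; full MCMC through the same adaptive Metropolis
sampler is available and cross-checked against the Laplace path on
synthetic data.  Evaluator random intercepts are integrated out of the
likelihood by 21-node Gauss-Hermite quadrature (evaluators are independent
given the fixed effects, so the integral factorizes per evaluator).  When
pointwise log-likelihoods are needed, group intercepts are re-sampled per
posterior draw from their conditional Laplace approximation — the usual
convention for multilevel LOO.

ELPD-LOO uses Pareto-smoothed importance sampling (arviz) on the pointwise
log-likelihood matrix, with per-observation Pareto-k diagnostics; more than
10% of observations above k = 0.7 attaches a warning.  The predictor screen
fits one single-predictor cumulative model per non-empty subset of the five
scaled metrics (31 candidates; singletons are the metrics themselves,
larger subsets are combined by average or minimum) and ranks them by ELPD,
with no multiplicity correction — it is a comparison, not a test.

Acceptance modeling dichotomizes scores (≤ 3 = accept) and fits Bernoulli
logits by maximum likelihood (statsmodels), reported with covariance-based
intervals.  The 50%-acceptance threshold of a metric is the analytic root
`−a/b` of the fitted logistic; its interval comes from normal draws of
`(a, b)`.  Results with the unexpected slope sign or a threshold outside
the observed metric range are flagged, never silently dropped.  The
rejection-reason model regresses the end-of-test vs time-course grouping
(records with scores ≥ 4 and a grouped reason only) on the four scaled
metrics; the representation model regresses acceptance on the DRC
indicator.

## Validation strategy and known limitations

* Forward model: analytic damage is checked against adaptive ODE
  integration at 1e−8 relative tolerance; SD with `b = 0` and IT with
  `mw → ∞` reduce exactly to background survival.
* Metrics: checked against naive-loop re-implementations at 1e−12 on 1000
  random fixtures, plus frozen hand-calculated examples.
* Calibration: parameter recovery on a benchmark design (5 treatments × 50
  organisms, 7 observation times mixing control, near-threshold and lethal
  constant exposures with single and double pulses, sub-daily early
  counts).  Even under this informative design the `kd`–`z`–`b` posterior
  ridge leaves single-dataset medians skewed by up to ~40% on unlucky
  draws while credible intervals still cover the truth; the recovery
  checks are therefore assessed per parameter across seeds.  Constant-only
  exposure designs are substantially worse and should not be used to
  calibrate `kd`.
* Survey chain: the full ordinal model recovers every generating fixed
  effect with near-nominal interval coverage across replicates, the
  evaluator SD within 30%, and the screen ranks the generating metric
  combination first (or within one standard error).
* PSIS-LOO is verified against exact leave-one-out refitting on a small
  dataset.

Limitations: the Laplace path slightly underestimates skewness of
cutpoint posteriors at small n (use MCMC there); the IT variant shares the
SD calibration machinery but the recovery benchmark is SD-only; the
synthetic survey does not model evaluator learning or custom free-text
reasons; and the acceptance thresholds computed on synthetic surveys
characterize the synthetic truth model, not any real evaluator population.
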