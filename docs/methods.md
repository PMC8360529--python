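# Methods

## Model

For a single site and stratum, daily event counts are modelled as

    Y_t ~ Poisson(μ_t),
    log μ_t = x_tᵀβ + b_t,

where the fixed-effect predictor `x_tᵀβ` contains

* an intercept;
* a natural cubic regression spline of calendar time, `NS(t, df_t)`,
  absorbing secular trend and slow unmeasured confounding;
* a natural cubic spline (or linear term) of the lag-weighted temperature
  `T̃_t = Σ_{l=0}^{6} w_l T_{t−l}` with `w` on the probability simplex;
* a linear PM10 term (optionally a spline), with relative humidity, SO₂
  and NO₂ available but off by default;
* six weekday contrasts against Monday;

and `b_t` is a stationary zero-mean AR(p) Gaussian process,
`b_t = Σ_k φ_k b_{t−k} + ε_t`, `ε_t ~ N(0, σ²)`, on the log-rate scale.
The latent process carries both the serial correlation of the counts and
their extra-Poisson variation; the observation model stays Poisson.

The first six days of the series lack a complete lag window and are
dropped from the analysis window.  A config flag moves the window to lags
1–7 (excluding the same day) for sensitivity analysis.

### Assumptions

* counts are conditionally Poisson given the smooth terms and `b_t`
  (overdispersion is not modelled at the fixed-effects stage — it is the
  latent process's job);
* the latent AR is stationary, and unmeasured confounding is slow enough
  for `NS(t, df_t)` to absorb;
* exposure acts through a single weighted-average temperature: no
  temperature-by-lag interaction surface.

## Estimation

Penalized quasi-likelihood (PQL) with alternating blocks, iterated until
the joint relative change of the fitted predictor, `w`, `φ` and `σ²`
drops below 1e−6 (at most 200 outer iterations; failure raises an error
carrying the iteration trace):

1. **(β, b) given (φ, σ², w).**  The Poisson IRLS linearization (working
   response `z = η + (Y−μ)/μ`, weights `W = μ`) turns the model into a
   working linear mixed model.  The joint penalized least-squares system
   is solved by block elimination: `(W + Q)` — with `Q` the banded AR(p)
   precision built from the innovations representation — is factorised
   sparsely, and β comes from the Schur complement.  The inner loop runs
   to a 1e−8 relative change in the penalized working criterion.
   `Cov(β)` is the inverse Schur complement (GLS covariance).
2. **(φ, σ²) given working residuals.**  Yule–Walker on
   `r = b̂ + (Y−μ̂)/μ̂`, with the known working-noise variance
   `mean(1/μ̂)` subtracted from the lag-0 autocovariance before solving.
   The correction matters: the working noise is serially independent, so
   it inflates only γ(0); uncorrected Yule–Walker attenuates φ severely.
   Non-stationary solutions are shrunk toward zero until all AR roots lie
   outside the unit circle (margin 0.02).  If the corrected γ(0) is
   indistinguishable from zero the latent signal is declared absent.
3. **Lag weights.**  The 6 free parameters of a softmax parameterisation
   (`w = softmax(0, θ₁…θ₆)`) take L-BFGS steps on the profiled working
   GLS objective `½(z − Xβ)ᵀV⁻¹(z − Xβ)` with `V = W⁻¹ + Σ_b` and β
   profiled out.  Integrating the latent out here is deliberate: holding
   `b̂` fixed lets it absorb part of the temperature signal and shrinks
   the weight estimate toward its starting point.  The envelope theorem
   gives the exact gradient through the slope of the fitted temperature
   smooth, chained through the softmax Jacobian.  Temperature-spline
   knots are held fixed during line searches and refreshed at the
   accepted point; once the weights stop moving they are frozen so the
   remaining blocks can settle.

With `p = 0` or `σ² = 0` the latent path is identically zero and the fit
reduces exactly to the fixed-effects GAM (tested to 1e−8).

### Lag-profile regularisation and multi-start

Unconstrained simplex weights estimated from ~1800 days are noisy: the
likelihood surface is multi-modal and sampling error favours jagged
profiles with spurious mass at isolated lags.  Two standard measures are
taken, in the spirit of constrained distributed-lag (Almon-type)
estimation:

* a second-difference smoothness penalty `λ‖Δ²w‖²` on the lag profile,
  default `λ = 300`.  The default was calibrated on simulations from the
  package's own generator and is insensitive over an order of magnitude
  (λ between 100 and 1000 behaves equivalently); it contributes at most a
  few log-likelihood units at smoothly decaying profiles while pricing
  jagged ones out;
* the whole alternating fit is restarted from four canonical lag shapes
  (uniform, linear decay, geometric, first-3-days block) and the winner
  is chosen by a Laplace approximation of the marginal log-likelihood
  (conditional log-likelihood minus latent penalty, log-determinant
  terms, and the weight penalty).

### Degree-of-freedom selection

* **Time spline (seasonal-pattern rule).**  For each candidate `df_t`
  (default grid 2–12 for a five-year series) the fixed-effects GAM is
  fitted and two quantities recorded: the amplitude (max − min) of the
  fitted temperature curve on the log scale, and the Wald χ² p-value of
  the temperature coefficient block.  Selected is the smallest candidate
  with p < 0.05 whose amplitude does not drop by more than half at the
  next larger candidate.  The principle: too little time-flexibility
  leaves confounding in the temperature curve, too much swallows the
  seasonal temperature signal itself (over-fitting).  The full
  per-candidate table is returned so the rule can be audited or
  overridden by a fixed `df_t` in config.
* **Covariate smooths.**  With `df_t` fixed, `df_temp` (and optionally
  `df_pm10`) are chosen by AIC over a grid, `AIC = 2k − 2ℓ` with `k`
  counting estimated coefficients plus estimated lag-weight parameters;
  ties break to the smaller df.  The AIC stage assumes Poisson
  dispersion, so it is run on the GAM before the latent process is added.

### AR-order selection

Candidates `p = 0 … p_max` (default 5) are fitted in turn.  A candidate
passes when

* the standardized one-step (Kalman innovation) residuals of the working
  response satisfy the whiteness criterion (|ACF| and |PACF| ≤ 0.10 at
  all lags 1–30), and
* the noise-corrected PACF of the latent component cuts off after `p`
  (no value above 0.10 at lags `p+1 … p_max`).

The innovation residuals are used because they are exactly white under a
correctly specified model, unlike smoothed-state residuals, which any
smoother leaves negatively autocorrelated.  The latent-PACF gate is
needed because measurement noise dilutes innovation autocorrelation: with
noise variance comparable to the latent variance, an AR(1) fit to AR(2)
data can pass innovation whiteness alone.  The smallest passing `p` is
returned; if none passes, `p_max` with a failure flag.

The 0.10 whiteness bound is a fixed practical criterion; the 1.96/√n
large-sample band is reported alongside but does not gate.

## Temperature effect, change points, zone risk ratios

The fitted temperature smooth is reported on a 200-point grid over the
observed range of `T̃`, centered at the central grid point, with
pointwise delta-method standard errors from the temperature-block GLS
covariance.  Change points are sign changes of the centered
finite-difference slope, de-duplicated to ≥ 3 °C separation, rounded to
1 °C, and capped at `df_temp − 1`.  Zone boundaries can also be supplied
directly (e.g. `--zones 12,26`).

The per-zone risk ratio is the exponentiated average slope per +1 °C,

    RR = exp[(f(u) − f(l)) / (u − l)],

with a 95% CI from the variance of the same linear contrast of spline
coefficients.  RRs depend only on differences of `f`, so they are
invariant to the centering reference.  The CIs treat the estimated lag
weights and AR parameters as fixed; this understates uncertainty
slightly.

## Forecasting

The fixed-effect predictor at future dates uses observed future
covariates — the model forecasts the health series, not the weather —
with the time spline continuing linearly beyond its training boundary
(the natural boundary condition).  The latent state is propagated by the
conditional-expectation recursion `b̂_{T+h} = Σ_k φ_k b̂_{T+h−k}` seeded
with the last `p` smoothed states; for stationary `φ` it decays
geometrically, so long-horizon forecasts converge to the fixed-effect
seasonal mean.  Nothing observed after the forecast origin enters the
prediction.  Validation is the Spearman rank correlation between
predicted means and observed counts.  No prediction intervals are
produced.

## Synthetic-data generator

Defaults emulate a five-year subtropical-metropolis series (the regime
the model targets): daily mean temperature as an annual sinusoid (mean
17.3 °C, amplitude 11 °C, peaking late July) plus an AR(1) anomaly
(marginal sd 3 °C, persistence 0.75 — multi-day synoptic weather);
PM10 ~ 80 μg/m³ base, negatively coupled to temperature with skewed
noise; humidity/SO₂/NO₂ as seasonal scenery; baseline ~90 events/day;
secular trend +5%/year; an unmeasured slow confounder (2.5-year wave,
amplitude 0.1 on the log scale) for the time spline to absorb; weekday
contrasts within ±0.05; true lag weights (0.4, 0.3, 0.15, 0.1, 0.05, 0,
0); latent AR(2) with φ = (0.5, 0.2) and σ² = 0.0132 (stationary sd 0.15,
i.e. roughly 3× Poisson overdispersion at this count level); true
temperature effect piecewise log-linear with per-°C slopes
log(0.988)/log(0.975)/log(0.999) in the zones below 12 °C, 12–26 °C and
above 26 °C.  The exposure series carries a 6-day lead-in so counts cover
exactly `n_days`.  All draws come from one seeded PCG64 generator; a seed
reproduces the dataset bit-identically.

What the generator deliberately does **not** emulate: calendar anomalies
(holidays, epidemics), reporting artifacts and missingness, volatility
clustering in weather, and measurement error in exposures.  Passing the
synthetic suite therefore demonstrates correctness of the estimation and
inference machinery under the model's own assumptions, not robustness to
real-data pathologies.  One visible consequence: the stationary AR(1)
temperature anomaly carries more independent high-frequency information
than real weather, so an over-flexible time spline only attenuates (does
not erase) the fitted temperature effect on synthetic data, whereas on
real series the erasure is typically complete.

## Numerical choices

* IRLS converges on relative deviance change < 1e−8 (max 100
  iterations); start `μ₀ = max(Y, 0.5) + 0.5`; rank deficiency is
  reported with the name of the collinear block.
* Spline columns are centered on the training sample (the intercept
  carries the level; fitted values unchanged); interior knots at equally
  spaced quantiles of the distinct predictor values, boundary knots at
  the observed range.
* Outer PQL tolerance 1e−6 on the fitted predictor and parameters;
  linear predictors are clipped at ±30 before exponentiation.
* Yule–Walker guards: corrected γ(0) floored at 0.1% of the raw γ(0);
  σ² floored at 1e−4·γ(0); stationarity projection margin 0.02.
* AIC ties break to the smaller df; identical designs give bitwise-equal
  AIC.
* Missing covariate values: linear interpolation across gaps of ≤ 3 days
  (flagged), error otherwise; missing counts on the analysis window are
  an error, never imputed.
* Dates are ISO-8601 calendar days; seasons are fixed by month (Mar–May
  spring, Jun–Aug summer, Sep–Nov autumn, Dec–Feb winter); years are
  calendar years.

## Problem sizes

The test suite and the acceptance script work at the study scale
(n = 1826 days) throughout; replicate counts are 20 seeds for recovery,
whiteness-contrast and forecast checks, and 50 for the AIC selection
frequency, sizes at which the medians and rates involved are stable.

## Known limitations

* PQL is an approximation: variance components carry the usual mild
  downward bias, and no marginal-likelihood maximisation (Laplace/AGQ) is
  attempted beyond the ranking criterion for multi-start.
* Effect-curve CIs condition on ŵ and φ̂.
* The GAM-stage AIC assumes Poisson dispersion; on strongly overdispersed
  data the df grid search can prefer flexibility (the mixed stage, not
  the AIC stage, handles overdispersion).
* Single site, single exposure window; no cross-basis (lag × temperature)
  surface, no attributable-fraction machinery, no prediction intervals.
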