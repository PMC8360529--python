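# mgam — mixed generalized additive models for environmental count series

`mgam` fits Poisson additive models with an autoregressive latent random
effect to daily health-event counts (emergency visits, hospitalisations)
driven by ambient temperature and air pollution.  It is written for
environmental-epidemiology time series where two things routinely break the
standard GLM/GAM toolkit:

1. **serial correlation** — daily counts are autocorrelated, so Poisson
   GAM standard errors and effect estimates are biased;
2. **arbitrary time-spline flexibility** — the customary "4 df per year"
   rule for the secular-trend spline can over-fit and erase the very
   temperature effect under study.

## The model

Daily counts follow a Poisson log-link mixed model

```
Y_t ~ Poisson(μ_t)
log μ_t = β0 + NS(t, df_t) + f(T̃_t; df_temp) + β·PM10_t + weekday_t + b_t
T̃_t    = Σ_{l=0..6} w_l · T_{t−l},      w_l ≥ 0, Σ w_l = 1
b_t     = φ1 b_{t−1} + … + φp b_{t−p} + ε_t,   ε_t ~ N(0, σ²)
```

* `NS(·, df)` are natural cubic regression splines (quantile interior
  knots, linear beyond the boundary);
* `T̃_t` is a 7-day weighted-average temperature whose simplex weights
  `w` are estimated jointly with the spline coefficients;
* `b_t` is a stationary AR(p) Gaussian process on the log-rate scale that
  absorbs serial correlation and extra-Poisson variation.

Estimation is penalized quasi-likelihood with alternating Newton-type
blocks (IRLS/GLS for coefficients and latent states, noise-corrected
Yule–Walker for (φ, σ²), quasi-Newton steps for the lag weights).  The
package also provides:

* a **seasonal-pattern rule** selecting `df_t` (smallest df that keeps the
  temperature effect significant and stable) and an **AIC grid search**
  for `df_temp`/`df_pm10`;
* **ACF/PACF whiteness diagnostics** with the fixed 0.10 criterion and
  AR-order selection;
* **temperature-zone risk ratios**: change points of the fitted spline
  split the temperature range into zones; each zone reports
  `RR = exp(average slope per +1 °C)` with a delta-method 95% CI;
* **out-of-sample forecasting** with latent-state propagation
  `b̂_{T+h} = Σ φ_k b̂_{T+h−k}` and Spearman validation;
* a **synthetic-data generator** with known truth (seasonal temperature,
  coupled PM10, latent AR(2), piecewise log-linear temperature effect)
  for end-to-end testing without any data download.

## Worked example

```python
import mgam

# five city-like years with known generating truth
exposure, counts, truth = mgam.simulate(seed=7)

model = mgam.MGAM(exposure, counts.stratum(),
                  spec=mgam.ModelSpec(df_time=5, df_temp=5), ar_order=2)
res = model.fit(estimate_weights=True)
print(res.summary())

report = res.diagnostics()          # ACF/PACF vs the 0.10 bound
curve = res.temperature_effect()    # log-rate effect of T̃ with SEs
rrs = mgam.zone_risk_ratios(curve, [12.0, 26.0])
```

This prints (abridged):

```
Mixed GAM (Poisson log link + AR latent random effect)
  n = 1826, fixed-effect k = 18, AR order p = 2
  phi = [ 0.5459,  0.1499]   sigma2 = 0.012100
  lag weights w0..w6 = [0.279, 0.238, 0.191, 0.145, 0.097, 0.051, 0.000]  (estimated)
  conditional logLik = -6318.31   AIC = 12690.62   R^2 = 0.9443
whiteness (|ACF|,|PACF| <= 0.10 at lags 1..30): PASS
zone  -0.8.. 12.0 C:  RR per +1C = 0.977 (95% CI 0.967-0.987)
zone  12.0.. 26.0 C:  RR per +1C = 0.975 (95% CI 0.972-0.978)
zone  26.0.. 33.5 C:  RR per +1C = 1.001 (95% CI 0.987-1.016)
```

The generator's true AR coefficients are (0.5, 0.2) and its true per-°C
risk ratios are 0.988 / 0.975 / 0.999 in the three zones: cold days carry
excess risk, risk falls fastest through the mid-range, and the warm zone
is flat.  The fitted AR parameters, the decaying lag-weight profile, the
white conditional residuals and the zone RRs all recover that structure;
`R²` is the squared Pearson correlation between fitted and observed daily
counts.

The same pipeline runs from the shell on CSV files:

```sh
mgam simulate --out-exposure exp.csv --out-counts cnt.csv --seed 7
mgam fit-mgam --exposure exp.csv --counts cnt.csv --order 2 --out model.json
mgam diagnose --model model.json --exposure exp.csv --counts cnt.csv --out diag.json
mgam effects  --model model.json --zones 12,26 --out effects.csv
mgam forecast --model model.json --exposure exp.csv \
              --from 2011-01-01 --to 2011-12-31 --out forecast.csv
```

To analyse real data, point `--exposure`/`--counts` at daily CSVs (a
`column_map` in the YAML config adapts any header dialect); `describe` and
`select-df` reproduce the descriptive tables and the df-selection reports.

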