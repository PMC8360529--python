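"""Out-of-sample forecasting of daily counts with AR latent propagation.

The fixed-effect predictor at future dates uses the observed future
covariates (the model forecasts the health series, not the weather); the
time spline continues linearly beyond its training boundary by the natural
boundary condition.  The latent state is propagated by the conditional-
expectation recursion of the fitted AR(p),

    b̂_{T+h} = Σ_k φ_k b̂_{T+h−k},

seeded with the last p smoothed states of the training fit; for a
stationary φ this decays geometrically to zero, so long-horizon forecasts
converge to the fixed-effect seasonal mean.  Nothing observed after the
forecast origin enters the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountSeries, ExposureSeries


@dataclass
class ForecastResult:
    """Daily forecast: predicted means, latent path and optional validation."""

    dates: pd.DatetimeIndex
    mu: np.ndarray
    latent: np.ndarray
    fixed_eta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "mu": self.mu, "latent": self.latent}
        ).set_index("date")

    def validate(self, observed) -> float:
        return validate(self, observed)


def propagate_latent(phi: np.ndarray, initial: np.ndarray,
                     horizon: int) -> np.ndarray:
    """AR conditional-mean recursion b̂_{T+h} = Σ φ_k b̂_{T+h−k}."""
    p = len(phi)
    if p == 0:
        return np.zeros(horizon)
    hist = list(np.asarray(initial, dtype=float)[-p:])
    if len(hist) < p:
        hist = [0.0] * (p - len(hist)) + hist
    out = np.empty(horizon)
    for h in range(horizon):
        val = float(np.dot(phi, hist[::-1][:p]))
        out[h] = val
        hist.append(val)
        hist = hist[-p:]
    return out


def predict(fit, future_exposure: ExposureSeries, dates) -> ForecastResult:
    """Forecast daily counts at ``dates`` from a fitted MGAM.

    ``future_exposure`` must cover the requested dates plus the 6-day lag
    lead-in.  Dates must lie strictly after the training window.
    """
    dates = pd.DatetimeIndex(dates)
    train_end = fit.frame.dates[-1]
    if dates.min() <= train_end:
        raise ValueError(
            f"forecast dates must start after the training window "
            f"(training ends {train_end.date()})"
        )
    d_new = fit.frame.design_new(fit.design, future_exposure, dates)
    fixed = d_new.X @ fit.params.to_numpy()

    p = fit.ar_params.p
    phi = fit.ar_params.phi
    # the recursion assumes a contiguous daily horizon from the origin
    offsets = (dates - train_end).days.to_numpy()
    horizon = int(offsets.max())
    latent_path = propagate_latent(
        phi, fit.latent_states[-max(p, 1):], horizon
    )
    latent = latent_path[offsets - 1]
    mu = np.exp(np.clip(fixed + latent, -30, 30))
    return ForecastResult(dates=dates, mu=mu, latent=latent,
                          fixed_eta=fixed)


def validate(forecast: ForecastResult, observed) -> float:
    """Spearman rank correlation between forecast means and observed counts."""
    if isinstance(observed, CountSeries):
        observed = observed.stratum()
    if isinstance(observed, pd.Series):
        observed = observed.reindex(forecast.dates)
        if observed.isna().any():
            raise ValueError("observed counts missing on forecast dates")
        observed = observed.to_numpy(dtype=float)
    else:
        observed = np.asarray(observed, dtype=float)
    if len(observed) != len(forecast.mu):
        raise ValueError("observed series not aligned with forecast")
    if np.all(observed == observed[0]):
        raise ValueError("degenerate observed series (all ties)")
    return float(stats.spearmanr(forecast.mu, observed).statistic)
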