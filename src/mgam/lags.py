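"""Distributed-lag construction for temperature exposure.

The effective exposure on day t is a weighted average of the mean
temperatures over a 7-day window, T̃_t = Σ_{l=0..6} w_l T_{t−l}, with the
weights w on the probability simplex (w_l ≥ 0, Σ w_l = 1).  By default the
window includes the same day (lags 0–6); set ``lag_includes_same_day=False``
for a 1–7 day window.  During estimation the weights are parameterised by a
softmax of 6 free parameters (the first logit pinned at zero), which keeps
Newton-type updates unconstrained while the reported weights stay on the
simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_LAGS = 7

#: default strength of the second-difference smoothness penalty applied to
#: the lag profile during estimation.  Unconstrained simplex weights are
#: noisy — sampling error produces jagged profiles with spurious mass at
#: isolated lags — so, as in polynomial/constrained distributed-lag
#: practice, estimation shrinks toward smoothly varying profiles.  The
#: default was calibrated on simulations from the package's own generator.
LAG_SMOOTHNESS = 300.0


def second_difference_matrix(n: int = N_LAGS) -> np.ndarray:
    """(n−2) × n matrix of second differences along the lag axis."""
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


@dataclass(frozen=True)
class LagWeights:
    """Simplex weights w_0 (same day) … w_6 (six days before)."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape != (N_LAGS,):
            raise ValueError(f"need exactly {N_LAGS} weights")
        if np.any(w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.6f})")
        object.__setattr__(self, "w", np.clip(w, 0.0, None))

    @classmethod
    def uniform(cls) -> "LagWeights":
        return cls(np.full(N_LAGS, 1.0 / N_LAGS))

    @classmethod
    def from_free(cls, theta: np.ndarray) -> "LagWeights":
        """Softmax map from 6 unconstrained parameters to the simplex."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_LAGS - 1,):
            raise ValueError(f"need {N_LAGS - 1} free parameters")
        logits = np.r_[0.0, theta]
        logits -= logits.max()
        e = np.exp(logits)
        return cls(e / e.sum())

    def to_free(self) -> np.ndarray:
        """Inverse softmax (weights floored away from zero for finiteness)."""
        w = np.clip(self.w, 1e-8, None)
        logits = np.log(w)
        return logits[1:] - logits[0]


def lag_matrix(exposure, column: str = "tmean") -> tuple[np.ndarray, np.ndarray]:
    """Build the n−6 × 7 lag matrix of a daily exposure column.

    Returns ``(L, dates)`` where row t, column l of ``L`` holds the value
    at day t−l.  The first 6 calendar days have incomplete windows and are
    excluded, so the analysis window starts on day 7 of the series.
    """
    from .io import ExposureSeries

    if isinstance(exposure, ExposureSeries):
        values = exposure.data[column].to_numpy(dtype=float)
        dates = exposure.dates
    else:
        values = np.asarray(exposure, dtype=float)
        dates = np.arange(len(values))
    if len(values) < N_LAGS:
        raise ValueError(f"need at least {N_LAGS} days")
    if np.isnan(values).any():
        raise ValueError("exposure series contains gaps")
    n = len(values) - (N_LAGS - 1)
    L = np.column_stack(
        [values[N_LAGS - 1 - l : N_LAGS - 1 - l + n] for l in range(N_LAGS)]
    )
    return L, dates[N_LAGS - 1 :]


def weighted_exposure(L: np.ndarray, weights: LagWeights) -> np.ndarray:
    """Weighted-average exposure T̃_t = Σ_l w_l T_{t−l} (units preserved)."""
    if not isinstance(weights, LagWeights):
        weights = LagWeights(np.asarray(weights, dtype=float))
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] != N_LAGS:
        raise ValueError(f"lag matrix must have {N_LAGS} columns")
    return L @ weights.w
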