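"""Autoregressive utilities for the latent random effect.

The latent process b_t follows a stationary zero-mean AR(p):

    b_t = φ_1 b_{t−1} + … + φ_p b_{t−p} + ε_t,   ε_t ~ N(0, σ²)

These helpers provide the stationary autocovariances, the (banded) precision
matrix of a length-n realisation, moment estimation of (φ, σ²) from noisy
observations of b, and the Kalman-filter one-step innovations used for
whiteness diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse
from statsmodels.tsa.arima_process import arma_acovf

#: required margin of AR roots outside the unit circle
STATIONARITY_MARGIN = 0.02


@dataclass(frozen=True)
class ArParams:
    """Order, coefficients and innovation variance of the latent AR."""

    p: int
    phi: np.ndarray
    sigma2: float

    def __post_init__(self):
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.p == 0:
            phi = np.zeros(0)
        if phi.shape != (self.p,):
            raise ValueError(f"phi must have length p={self.p}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.p > 0 and not is_stationary(phi):
            raise ValueError(f"non-stationary AR coefficients {phi}")
        object.__setattr__(self, "phi", phi)

    @property
    def stationary_variance(self) -> float:
        if self.p == 0 or self.sigma2 == 0:
            return self.sigma2
        return float(autocovariances(self.phi, self.sigma2, 0)[0])


def is_stationary(phi, margin: float = 0.0) -> bool:
    """True if all roots of 1 − φ_1 z − … − φ_p z^p lie outside the unit
    circle (by at least ``margin``)."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 0 or not np.any(phi):
        return True
    roots = np.roots(np.r_[-phi[::-1], 1.0])
    return bool(np.all(np.abs(roots) > 1.0 + margin))


def project_to_stationarity(phi, margin: float = STATIONARITY_MARGIN):
    """Shrink φ toward zero until the AR polynomial is safely stationary."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    scale = 1.0
    for _ in range(60):
        if is_stationary(scale * phi, margin):
            return scale * phi, scale != 1.0
        scale *= 0.95
    return np.zeros_like(phi), True


def autocovariances(phi, sigma2: float, max_lag: int) -> np.ndarray:
    """Stationary autocovariances γ_0 … γ_max_lag of an AR(p)."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    ar = np.r_[1.0, -phi]
    return arma_acovf(ar, np.array([1.0]), nobs=max_lag + 1, sigma2=sigma2)


def innovations_matrix(params: ArParams, n: int) -> sparse.csr_matrix:
    """Sparse lower-banded B with B b ~ N(0, σ² I) for b a length-n AR(p)
    path; hence the precision of b is BᵀB / σ²."""
    p, phi, sigma2 = params.p, params.phi, params.sigma2
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive for a precision matrix")
    B = sparse.lil_matrix((n, n))
    if p > 0:
        gam = autocovariances(phi, sigma2, p - 1)
        Gp = linalg.toeplitz(gam[:p])
        L = linalg.cholesky(Gp, lower=True)
        B[:p, :p] = np.sqrt(sigma2) * linalg.solve_triangular(
            L, np.eye(p), lower=True
        )
    for t in range(p, n):
        B[t, t] = 1.0
        for k in range(1, p + 1):
            B[t, t - k] = -phi[k - 1]
    return B.tocsr()


def precision(params: ArParams, n: int) -> sparse.csr_matrix:
    """Banded precision matrix (bandwidth p) of a length-n AR(p) path."""
    B = innovations_matrix(params, n)
    return (B.T @ B) / params.sigma2


def sample_autocovariance(x, max_lag: int) -> np.ndarray:
    """Biased (denominator n) mean-centered sample autocovariances."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be < series length")
    xc = x - x.mean()
    return np.array(
        [xc[: n - k] @ xc[k:] / n for k in range(max_lag + 1)]
    )


def corrected_yule_walker(
    resid, order: int, measurement_var: float = 0.0
) -> ArParams:
    """Yule–Walker estimate of (φ, σ²) from observations b_t + e_t.

    The observed series is the latent AR path plus independent measurement
    noise of known average variance (for a Poisson working response,
    mean(1/μ̂)).  Noise inflates only the lag-0 autocovariance, so the
    Yule–Walker equations are solved with γ̂(0) replaced by
    γ̂(0) − measurement_var.  Non-stationary solutions are projected back
    inside the unit circle.
    """
    resid = np.asarray(resid, dtype=float)
    if order == 0:
        return ArParams(0, np.zeros(0), 0.0)
    gam = sample_autocovariance(resid, order)
    g0 = gam[0] - measurement_var
    # latent variance indistinguishable from zero -> no usable AR signal
    floor = max(1e-3 * gam[0], 1e-12)
    if g0 < floor:
        return ArParams(order, np.zeros(order), max(g0, floor))
    g = np.r_[g0, gam[1:]]
    G = linalg.toeplitz(g[:order])
    try:
        phi = linalg.solve(G, g[1 : order + 1], assume_a="pos")
    except linalg.LinAlgError:
        phi = np.linalg.lstsq(G, g[1 : order + 1], rcond=None)[0]
    phi, _ = project_to_stationarity(phi)
    sigma2 = float(g0 - phi @ g[1 : order + 1])
    sigma2 = max(sigma2, 1e-4 * g0)
    return ArParams(order, phi, sigma2)


def kalman_innovations(
    y, params: ArParams, obs_var
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized one-step prediction errors of y_t = b_t + e_t.

    ``obs_var`` is the per-observation variance of e_t (scalar or length-n).
    Returns ``(nu, F)``: standardized innovations ν_t/√F_t and the
    innovation variances.  Under a correctly specified model the
    standardized innovations are white noise, which makes them the natural
    input to ACF/PACF whiteness checks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    obs_var = np.broadcast_to(np.asarray(obs_var, dtype=float), (n,))
    p = params.p
    if p == 0 or params.sigma2 <= 0:
        F = obs_var + params.sigma2
        return y / np.sqrt(F), F

    phi, sigma2 = params.phi, params.sigma2
    T = np.zeros((p, p))
    T[0, :] = phi
    if p > 1:
        T[1:, :-1] = np.eye(p - 1)
    Z = np.zeros(p)
    Z[0] = 1.0
    Qs = np.zeros((p, p))
    Qs[0, 0] = sigma2

    gam = autocovariances(phi, sigma2, p - 1) if p > 0 else np.array([sigma2])
    P = linalg.toeplitz(gam[:p])
    x = np.zeros(p)
    nu = np.empty(n)
    F = np.empty(n)
    for t in range(n):
        Ft = P[0, 0] + obs_var[t]
        vt = y[t] - x[0]
        nu[t] = vt / np.sqrt(Ft)
        F[t] = Ft
        K = P[:, 0] / Ft
        x = T @ (x + K * vt)
        P_upd = P - np.outer(K, P[0, :])
        P = T @ P_upd @ T.T + Qs
        P = (P + P.T) / 2
    return nu, F


def simulate_ar(params: ArParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a stationary AR(p) path of length n (exact stationary start)."""
    p, phi, sigma2 = params.p, params.phi, params.sigma2
    if sigma2 == 0 or (p == 0):
        if sigma2 == 0:
            return np.zeros(n)
        return rng.normal(0.0, np.sqrt(sigma2), n)
    gam = autocovariances(phi, sigma2, p - 1)
    Gp = linalg.toeplitz(gam[:p])
    L = linalg.cholesky(Gp, lower=True)
    b = np.empty(n)
    b[:p] = L @ rng.normal(size=p)
    eps = rng.normal(0.0, np.sqrt(sigma2), n)
    for t in range(p, n):
        b[t] = phi @ b[t - p : t][::-1] + eps[t]
    return b
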