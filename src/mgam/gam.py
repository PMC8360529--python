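"""Fixed-effects Poisson GAM fitted by iteratively reweighted least squares.

The model is a Poisson log-link regression whose design holds regression
splines (natural cubic, fixed df) for time and for the lag-weighted
temperature, linear pollutant terms and weekday contrasts.  IRLS is the
Newton method for this likelihood; convergence is declared when the
relative deviance change falls below ``tol`` (default 1e-8).

Lag weights can optionally be profiled out: for each candidate simplex
weight vector the spline coefficients are re-estimated by IRLS, and the
6 free softmax parameters are moved by a quasi-Newton method on the
profiled log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .design import Design, ModelFrame, ModelSpec
from .io import CountSeries, ExposureSeries
from .lags import LagWeights


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y / mu, 1.0)), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _check_rank(X: np.ndarray, names, blocks) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # locate the offending block by dropping blocks one at a time
    for name, sl in blocks.items():
        keep = np.ones(X.shape[1], bool)
        keep[sl] = False
        if np.linalg.matrix_rank(X[:, keep]) == rank:
            raise RankDeficiencyError(
                f"design is rank deficient; block {name!r} is collinear "
                f"with the rest of the design"
            )
    raise RankDeficiencyError("design is rank deficient")


def irls_poisson(
    X: np.ndarray,
    y: np.ndarray,
    offset=0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    names=None,
    blocks=None,
) -> dict:
    """Maximum-likelihood Poisson log-link fit by IRLS.

    Returns coefficients, fitted means, the inverse Fisher information,
    deviance/log-likelihood and the per-iteration deviance trace.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (n,))
    mu = np.clip(y, 0.5, None) + 0.5
    eta = np.log(mu)
    dev = poisson_deviance(y, mu)
    trace = [dev]
    beta = np.zeros(k)
    for _ in range(max_iter):
        W = mu
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(W)
        Xw = X * sw[:, None]
        zw = z * sw
        beta_new, _, rank, _ = np.linalg.lstsq(Xw, zw, rcond=None)
        if rank < k:
            _check_rank(Xw, names, blocks or {})
        eta = X @ beta_new + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        beta = beta_new
        dev_new = poisson_deviance(y, mu)
        trace.append(dev_new)
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            dev = dev_new
            break
        dev = dev_new
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", trace=trace
        )
    XtWX = (X * mu[:, None]).T @ X
    cov = np.linalg.pinv(XtWX)
    return {
        "beta": beta,
        "mu": mu,
        "eta": eta,
        "cov": cov,
        "deviance": dev,
        "loglik": poisson_loglik(y, mu),
        "trace": np.asarray(trace),
        "n_iter": len(trace) - 1,
    }


def profile_weight_step(
    frame: ModelFrame,
    theta: np.ndarray,
    temp_basis,
    offset,
    maxiter: int = 8,
    lag_penalty: float = None,
) -> np.ndarray:
    """Quasi-Newton steps on the lag-weight free parameters.

    The objective is the Poisson log-likelihood with the spline/covariate
    coefficients profiled out by IRLS at each candidate weight vector (the
    latent path, when present, enters as a fixed offset).  By the envelope
    theorem the profiled gradient needs no coefficient derivatives:

        dℓ/dw = Lᵀ[(y − μ) ⊙ f'(T̃)],

    chained through the softmax Jacobian; f' is the slope of the fitted
    temperature smooth.  A second-difference smoothness penalty on the lag
    profile regularises the otherwise noisy simplex estimate.  Temperature-
    spline knots are held fixed here and refreshed by the caller between
    passes.
    """
    from .lags import LAG_SMOOTHNESS, second_difference_matrix

    y = frame.y
    lam = LAG_SMOOTHNESS if lag_penalty is None else lag_penalty
    D = second_difference_matrix()
    DtD = D.T @ D

    def obj_and_grad(th):
        w = LagWeights.from_free(th)
        d = frame.design(w, temp_basis=temp_basis, refresh_knots=False)
        res = irls_poisson(d.X, y, offset=offset, tol=1e-10, max_iter=100)
        beta = res["beta"]
        mu = res["mu"]
        bt = beta[d.block("temp")]
        if d.temp_basis is None:
            slope = np.full(frame.n, bt[0])
        else:
            slope = d.temp_basis.derivative(d.exposure_weighted) @ bt
        g_w = frame.L.T @ ((y - mu) * slope)
        wv = w.w
        J = wv[:, None] * (np.eye(len(wv))[:, 1:] - wv[None, 1:])
        pen = lam * float(wv @ DtD @ wv)
        pen_grad = 2.0 * lam * (DtD @ wv) @ J
        return -res["loglik"] + pen, -(g_w @ J) + pen_grad

    opt = optimize.minimize(
        obj_and_grad, theta, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )
    return opt.x


@dataclass
class GAMResults:
    """Fitted fixed-effects Poisson GAM."""

    frame: ModelFrame = field(repr=False)
    design: Design = field(repr=False)
    params: pd.Series
    cov_params: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    deviance: float
    loglik: float
    converged: bool
    n_iter: int
    trace: np.ndarray = field(repr=False)
    weights_estimated: bool = False

    @property
    def spec(self) -> ModelSpec:
        return self.frame.spec

    @property
    def lag_weights(self) -> LagWeights:
        return self.design.weights

    @property
    def k_params(self) -> int:
        k = len(self.params)
        if self.weights_estimated:
            k += len(self.design.weights.w) - 1
        return k

    @property
    def aic(self) -> float:
        """Akaike information criterion 2k − 2·loglik; k counts estimated
        coefficients plus the free lag-weight parameters when profiled."""
        return 2.0 * self.k_params - 2.0 * self.loglik

    def block_params(self, name: str) -> np.ndarray:
        return self.params.to_numpy()[self.design.block(name)]

    def block_cov(self, name: str) -> np.ndarray:
        sl = self.design.block(name)
        return self.cov_params[sl, sl]

    def wald_test(self, block: str) -> tuple[float, int, float]:
        """Wald chi-square test that an entire coefficient block is zero."""
        beta = self.block_params(block)
        cov = self.block_cov(block)
        stat = float(beta @ np.linalg.solve(cov, beta))
        df = len(beta)
        return stat, df, float(stats.chi2.sf(stat, df))

    def residuals(self, kind: str = "pearson_marginal") -> np.ndarray:
        """Pearson residuals (Y − μ̂)/√μ̂ of the fixed-effects fit."""
        if kind not in ("pearson_marginal", "conditional"):
            raise ValueError(f"unknown residual kind {kind!r}")
        return (self.frame.y - self.mu) / np.sqrt(self.mu)

    def temperature_effect(self, n_grid: int = 200):
        from .effects import temperature_effect

        return temperature_effect(self, n_grid=n_grid)

    def fixed_predictor(self, exposure: ExposureSeries, dates) -> np.ndarray:
        """Linear predictor at new dates from the fitted fixed effects."""
        d = self.frame.design_new(self.design, exposure, pd.DatetimeIndex(dates))
        return d.X @ self.params.to_numpy()

    def summary(self) -> str:
        lines = [
            "Poisson GAM (log link)",
            f"  n = {self.frame.n}, k = {self.k_params}",
            f"  deviance = {self.deviance:.2f}   logLik = {self.loglik:.2f}   "
            f"AIC = {self.aic:.2f}",
            f"  lag weights: "
            + " ".join(f"{w:.3f}" for w in self.lag_weights.w)
            + ("  (estimated)" if self.weights_estimated else "  (fixed)"),
            "  coefficients:",
        ]
        se = np.sqrt(np.diag(self.cov_params))
        for i, (name, b) in enumerate(self.params.items()):
            lines.append(f"    {name:<12} {b:>10.5f}  (se {se[i]:.5f})")
        return "\n".join(lines)


class PoissonGAM:
    """Fixed-effects Poisson additive model for daily event counts.

    Parameters
    ----------
    exposure : ExposureSeries
    counts : CountSeries or pandas.Series
        Daily counts (one stratum) indexed by date.
    spec : ModelSpec
    weights : LagWeights, optional
        Lag weights for the temperature exposure; defaults to uniform 1/7.
    """

    def __init__(self, exposure, counts, spec: ModelSpec | None = None,
                 weights: LagWeights | None = None):
        self.spec = spec or ModelSpec()
        self.frame = ModelFrame(exposure, counts, self.spec)
        self.weights = weights or LagWeights.uniform()

    @classmethod
    def from_dataframes(cls, exposure_df: pd.DataFrame, counts: pd.Series,
                        spec: ModelSpec | None = None, **kw) -> "PoissonGAM":
        return cls(ExposureSeries(exposure_df), counts, spec=spec, **kw)

    def fit(
        self,
        estimate_weights: bool = False,
        tol: float = 1e-8,
        max_iter: int = 100,
    ) -> GAMResults:
        frame = self.frame
        weights = self.weights
        design = frame.design(weights)
        if estimate_weights:
            theta = weights.to_free()
            for _ in range(5):  # refresh temperature knots between passes
                theta_new = profile_weight_step(
                    frame, theta, design.temp_basis, offset=0.0, maxiter=40
                )
                moved = np.max(np.abs(theta_new - theta))
                theta = theta_new
                weights = LagWeights.from_free(theta)
                design = frame.design(weights)
                if moved < 1e-7:
                    break
        res = irls_poisson(
            design.X, frame.y, tol=tol, max_iter=max_iter,
            names=design.names, blocks=design.blocks,
        )
        return GAMResults(
            frame=frame,
            design=design,
            params=pd.Series(res["beta"], index=design.names),
            cov_params=res["cov"],
            mu=res["mu"],
            eta=res["eta"],
            deviance=res["deviance"],
            loglik=res["loglik"],
            converged=True,
            n_iter=res["n_iter"],
            trace=res["trace"],
            weights_estimated=estimate_weights,
        )


def fit_gam(
    exposure,
    counts,
    spec: ModelSpec | None = None,
    weights: LagWeights | None = None,
    estimate_weights: bool = False,
) -> GAMResults:
    """Convenience wrapper: build a :class:`PoissonGAM` and fit it."""
    return PoissonGAM(exposure, counts, spec=spec, weights=weights).fit(
        estimate_weights=estimate_weights
    )
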