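"""Mixed generalized additive model: Poisson GAM + AR(p) latent effect.

The observation model is

    Y_t ~ Poisson(μ_t),   log μ_t = x_tᵀβ + b_t,

where x_tᵀβ is the GAM fixed-effect predictor (time spline, temperature
spline on the lag-weighted exposure, pollutant terms, weekday contrasts)
and b_t is a stationary zero-mean AR(p) Gaussian process that absorbs the
serial correlation and extra-Poisson variation of the daily counts.

Estimation is penalized quasi-likelihood with alternating blocks:

1. given (φ, σ²) and the lag weights, the Poisson IRLS linearization turns
   the model into a working linear mixed model; (β, b) solve the penalized
   weighted least-squares system whose penalty is the banded AR precision;
2. given the working residuals, (φ, σ²) are re-estimated by Yule–Walker
   with the known working-noise variance removed from the lag-0
   autocovariance (the noise is serially independent, so it inflates only
   γ(0));
3. given everything else, the 6 free softmax parameters of the lag weights
   take quasi-Newton steps on the profiled Poisson log-likelihood.

The blocks repeat until the joint relative parameter change drops below
1e-6.  With σ² = 0 or p = 0 the latent path is identically zero and the
fit reduces exactly to the fixed-effects GAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from . import ar as ar_mod
from .ar import ArParams
from .design import Design, ModelFrame, ModelSpec
from .diagnostics import (DEFAULT_MAX_LAG, WHITENESS_THRESHOLD,
                          DiagnosticsReport, whiteness_check)
from .gam import (ConvergenceError, GAMResults, PoissonGAM, irls_poisson,
                  poisson_deviance, poisson_loglik)
from .io import CountSeries, ExposureSeries
from .lags import LagWeights

_SIGMA2_FLOOR = 1e-10


def _pql_inner(X, y, ar_params: ArParams, eta0, tol=1e-8, max_iter=60):
    """Penalized IRLS for (β, b) at fixed AR parameters.

    Solves the working linear mixed model by block elimination: the banded
    system (W + Q) is factorised sparsely, where Q is the AR precision.
    Returns coefficients, latent states, fitted means, the GLS covariance
    of β and the final working response/weights.
    """
    n, k = X.shape
    no_latent = ar_params.p == 0 or ar_params.sigma2 <= _SIGMA2_FLOOR
    if no_latent:
        res = irls_poisson(X, y, tol=tol, max_iter=max_iter)
        return {
            "beta": res["beta"], "b": np.zeros(n), "mu": res["mu"],
            "eta": res["eta"], "cov_beta": res["cov"], "z": None,
            "w_work": res["mu"], "n_iter": res["n_iter"],
        }

    Q = ar_mod.precision(ar_params, n)
    eta = np.asarray(eta0, dtype=float).copy()
    mu = np.exp(np.clip(eta, -30, 30))
    crit_prev = None
    beta = np.zeros(k)
    b = np.zeros(n)
    for it in range(max_iter):
        W = mu
        z = eta + (y - mu) / mu
        A = (diags(W) + Q).tocsc()
        solver = splu(A)
        WX = X * W[:, None]
        M = solver.solve(WX)
        S = X.T @ WX - WX.T @ M
        rhs = X.T @ (W * z) - WX.T @ solver.solve(W * z)
        beta = np.linalg.solve(S, rhs)
        b = solver.solve(W * (z - X @ beta))
        eta = np.clip(X @ beta + b, -30, 30)
        mu = np.exp(eta)
        # penalized working criterion: deviance + latent quadratic penalty
        crit = poisson_deviance(y, mu) + float(b @ (Q @ b))
        if crit_prev is not None and abs(crit_prev - crit) <= tol * (
            abs(crit) + 0.1
        ):
            crit_prev = crit
            break
        crit_prev = crit
    cov_beta = np.linalg.pinv(S)
    return {
        "beta": beta, "b": b, "mu": mu, "eta": eta, "cov_beta": cov_beta,
        "z": z, "w_work": W, "n_iter": it + 1,
    }


@dataclass
class MGAMResults:
    """Fitted mixed GAM: fixed effects, lag weights, AR parameters and the
    smoothed latent path."""

    frame: ModelFrame = field(repr=False)
    design: Design = field(repr=False)
    params: pd.Series
    cov_params: np.ndarray = field(repr=False)
    lag_weights: LagWeights
    ar_params: ArParams
    latent_states: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    converged: bool
    n_iter: int
    trace: pd.DataFrame = field(repr=False)
    weights_estimated: bool = False

    @property
    def spec(self) -> ModelSpec:
        return self.frame.spec

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.dates

    @property
    def fixed_eta(self) -> np.ndarray:
        return self.eta - self.latent_states

    @property
    def mu_fixed(self) -> np.ndarray:
        """Fitted means from the fixed effects alone (b set to zero)."""
        return np.exp(self.fixed_eta)

    @property
    def loglik_conditional(self) -> float:
        return poisson_loglik(self.frame.y, self.mu)

    @property
    def k_params(self) -> int:
        k = len(self.params) + self.ar_params.p + (
            1 if self.ar_params.sigma2 > 0 else 0
        )
        if self.weights_estimated:
            k += len(self.lag_weights.w) - 1
        return k

    @property
    def aic(self) -> float:
        """Conditional-likelihood AIC (fixed + AR + weight parameters)."""
        return 2.0 * self.k_params - 2.0 * self.loglik_conditional

    def r_squared(self, observed=None) -> float:
        """Squared Pearson correlation between fitted and observed counts."""
        y = self.frame.y if observed is None else np.asarray(observed, float)
        if len(y) != len(self.mu):
            raise ValueError("observed series not aligned with the fit")
        if np.std(self.mu) == 0 or np.std(y) == 0:
            raise ValueError("zero-variance input to r_squared")
        r = np.corrcoef(self.mu, y)[0, 1]
        return float(r * r)

    def block_params(self, name: str) -> np.ndarray:
        return self.params.to_numpy()[self.design.block(name)]

    def block_cov(self, name: str) -> np.ndarray:
        sl = self.design.block(name)
        return self.cov_params[sl, sl]

    def wald_test(self, block: str) -> tuple[float, int, float]:
        from scipy import stats

        beta = self.block_params(block)
        cov = self.block_cov(block)
        stat = float(beta @ np.linalg.solve(cov, beta))
        return stat, len(beta), float(stats.chi2.sf(stat, len(beta)))

    # ---- residuals ----------------------------------------------------

    def residuals(self, kind: str = "conditional") -> np.ndarray:
        """Residual series for diagnostics.

        ``pearson_marginal``
            (Y − μ̂_fixed)/√μ̂_fixed with the latent path excluded; shows
            the serial correlation a fixed-effects GAM leaves behind.
        ``conditional``
            standardized one-step (innovation) residuals of the working
            response under the fitted latent AR + working-noise model;
            white when the latent model is adequate.
        ``conditional_smoothed``
            working residual minus the smoothed latent path; retains the
            negative serial correlation that any smoother induces, kept
            for plotting/inspection only.
        """
        y = self.frame.y
        if kind == "pearson_marginal":
            mf = self.mu_fixed
            return (y - mf) / np.sqrt(mf)
        work_resid = self._working_residual()
        if kind == "conditional_smoothed":
            return work_resid - self.latent_states
        if kind == "conditional":
            if self.ar_params.sigma2 <= _SIGMA2_FLOOR or self.ar_params.p == 0:
                return (y - self.mu) / np.sqrt(self.mu)
            nu, _ = ar_mod.kalman_innovations(
                work_resid, self.ar_params, 1.0 / self.mu
            )
            return nu
        raise ValueError(f"unknown residual kind {kind!r}")

    def _working_residual(self) -> np.ndarray:
        """Working-scale residual z − Xβ̂ = b̂ + (Y − μ̂)/μ̂."""
        return self.latent_states + (self.frame.y - self.mu) / self.mu

    def diagnostics(
        self,
        threshold: float = WHITENESS_THRESHOLD,
        max_lag: int = DEFAULT_MAX_LAG,
        kind: str = "conditional",
    ) -> DiagnosticsReport:
        return whiteness_check(
            self.residuals(kind), threshold=threshold, max_lag=max_lag
        )

    def latent_pacf(self, max_lag: int = 6) -> np.ndarray:
        """Noise-corrected PACF of the latent component of the working
        residual; its cutoff identifies the AR order."""
        from .diagnostics import noise_corrected_pacf

        return noise_corrected_pacf(
            self._working_residual(),
            measurement_var=float(np.mean(1.0 / self.mu)),
            max_lag=max_lag,
        )

    # ---- prediction ----------------------------------------------------

    def predict(self, future_exposure: ExposureSeries, dates):
        from .forecast import predict

        return predict(self, future_exposure, dates)

    def temperature_effect(self, n_grid: int = 200):
        from .effects import temperature_effect

        return temperature_effect(self, n_grid=n_grid)

    def summary(self) -> str:
        w = self.lag_weights.w
        lines = [
            "Mixed GAM (Poisson log link + AR latent random effect)",
            f"  n = {self.frame.n}, fixed-effect k = {len(self.params)}, "
            f"AR order p = {self.ar_params.p}",
            f"  phi = [" + ", ".join(f"{v: .4f}" for v in self.ar_params.phi)
            + f"]   sigma2 = {self.ar_params.sigma2:.6f}",
            "  lag weights w0..w6 = ["
            + ", ".join(f"{v:.3f}" for v in w) + "]"
            + ("  (estimated)" if self.weights_estimated else "  (fixed)"),
            f"  conditional logLik = {self.loglik_conditional:.2f}   "
            f"AIC = {self.aic:.2f}   R^2 = {self.r_squared():.4f}",
            "  coefficients:",
        ]
        se = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))
        for i, (name, bval) in enumerate(self.params.items()):
            lines.append(f"    {name:<12} {bval:>10.5f}  (se {se[i]:.5f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable dump sufficient to reload and predict
        bit-identically (see :mod:`mgam.persist`)."""
        from .persist import model_state

        return model_state(self)

    def save(self, path) -> None:
        from .persist import save_model

        save_model(self, path)


class MGAM:
    """Mixed generalized additive model for daily environmental counts.

    Parameters
    ----------
    exposure : ExposureSeries
    counts : CountSeries or pandas.Series
    spec : ModelSpec, optional
        Degrees of freedom and covariate switches (df values should already
        have been selected, e.g. by :func:`mgam.selection.select_df_time`).
    ar_order : int
        Order p ≥ 0 of the latent autoregression; p = 0 is the plain GAM.
    weights : LagWeights, optional
        Starting (or fixed) lag weights; uniform 1/7 by default.
    """

    def __init__(self, exposure, counts, spec: ModelSpec | None = None,
                 ar_order: int = 2, weights: LagWeights | None = None):
        self.spec = spec or ModelSpec()
        self.frame = ModelFrame(exposure, counts, self.spec)
        self.ar_order = int(ar_order)
        if self.ar_order < 0:
            raise ValueError("ar_order must be >= 0")
        self.weights = weights or LagWeights.uniform()

    @classmethod
    def from_dataframes(cls, exposure_df, counts, **kw) -> "MGAM":
        return cls(ExposureSeries(exposure_df), counts, **kw)

    def fit(
        self,
        estimate_weights: bool = False,
        fix_ar: ArParams | None = None,
        tol: float = 1e-6,
        max_iter: int = 200,
        inner_tol: float = 1e-8,
    ) -> MGAMResults:
        """Fit the mixed model.

        When lag weights are estimated the profiled objective can be
        multi-modal, so the alternating scheme is restarted from a few
        canonical lag-weight shapes and the fit with the best Laplace
        approximation of the marginal likelihood is kept.
        """
        if not estimate_weights:
            return self._fit_once(self.weights, False, fix_ar, tol,
                                  max_iter, inner_tol)
        starts = [self.weights] + [
            LagWeights(w0) for w0 in self._WEIGHT_STARTS
            if np.max(np.abs(w0 - self.weights.w)) > 1e-9
        ]
        best = None
        best_score = -np.inf
        errors = []
        for w0 in starts:
            try:
                res = self._fit_once(w0, True, fix_ar, tol, max_iter,
                                     inner_tol)
            except ConvergenceError as exc:
                errors.append(exc)
                continue
            score = self._laplace_criterion(res)
            if score > best_score:
                best, best_score = res, score
        if best is None:
            raise errors[0]
        return best

    def _fit_once(
        self,
        weights: LagWeights,
        estimate_weights: bool,
        fix_ar: ArParams | None,
        tol: float,
        max_iter: int,
        inner_tol: float,
    ) -> MGAMResults:
        frame = self.frame
        y = frame.y
        p = self.ar_order if fix_ar is None else fix_ar.p

        # --- initialization: fixed-effects GAM at the starting weights
        design = frame.design(weights)
        gam = irls_poisson(design.X, y, names=design.names,
                           blocks=design.blocks)
        beta, mu, eta = gam["beta"], gam["mu"], gam["eta"]
        b = np.zeros(frame.n)
        if fix_ar is not None:
            ar_params = fix_ar
        elif p == 0:
            ar_params = ArParams(0, np.zeros(0), 0.0)
        else:
            r0 = (y - mu) / mu
            ar_params = ar_mod.corrected_yule_walker(
                r0, p, measurement_var=float(np.mean(1.0 / mu))
            )

        theta = weights.to_free() if estimate_weights else None
        weights_locked = False
        trace_rows = []
        converged = False
        state = self._state_vector(eta, ar_params, weights)
        for outer in range(max_iter):
            inner = _pql_inner(design.X, y, ar_params, eta, tol=inner_tol)
            beta, b = inner["beta"], inner["b"]
            mu, eta = inner["mu"], inner["eta"]
            cov_beta = inner["cov_beta"]

            if fix_ar is None and p > 0:
                work_resid = b + (y - mu) / mu
                new_ar = ar_mod.corrected_yule_walker(
                    work_resid, p, measurement_var=float(np.mean(1.0 / mu))
                )
                ar_params = new_ar

            if estimate_weights and not weights_locked:
                w_old = weights.w
                z = inner["z"]
                if z is None:  # degenerate (no-latent) path
                    z = eta + (y - mu) / mu
                theta, weights, design = self._update_weights(
                    theta, design, z, inner["w_work"], ar_params,
                )
                # once the weights stop moving, freeze them (and the
                # temperature knots) so the remaining blocks can settle
                if np.max(np.abs(weights.w - w_old)) < 1e-6:
                    weights_locked = True
                # refit beta at new design with latent offset
                refit = irls_poisson(design.X, y, offset=b)
                beta, mu = refit["beta"], refit["mu"]
                eta = np.clip(design.X @ beta + b, -30, 30)
                mu = np.exp(eta)

            new_state = self._state_vector(eta, ar_params, weights)
            delta = np.max(np.abs(new_state - state)) / (
                1.0 + np.max(np.abs(new_state))
            )
            trace_rows.append({
                "outer": outer, "delta": delta,
                "sigma2": ar_params.sigma2,
                "deviance": poisson_deviance(y, mu),
                "inner_iter": inner["n_iter"],
            })
            state = new_state
            if delta < tol:
                converged = True
                break

        if not converged:
            raise ConvergenceError(
                f"MGAM did not converge in {max_iter} outer iterations "
                f"(last relative change {delta:.2e})",
                trace=pd.DataFrame(trace_rows),
            )

        # final consolidated solve at the converged parameters
        inner = _pql_inner(design.X, y, ar_params, eta, tol=inner_tol)
        return MGAMResults(
            frame=frame,
            design=design,
            params=pd.Series(inner["beta"], index=design.names),
            cov_params=inner["cov_beta"],
            lag_weights=weights,
            ar_params=ar_params,
            latent_states=inner["b"],
            mu=inner["mu"],
            eta=inner["eta"],
            converged=True,
            n_iter=outer + 1,
            trace=pd.DataFrame(trace_rows),
            weights_estimated=estimate_weights,
        )

    @staticmethod
    def _state_vector(eta, ar_params: ArParams, weights: LagWeights):
        # convergence is judged on the fitted predictor rather than raw
        # coefficients: refreshing spline knots reparameterises the basis
        # without changing the fit
        return np.r_[eta, ar_params.phi, ar_params.sigma2, weights.w]

    #: canonical starting shapes for whole-fit multi-start over lag weights
    _WEIGHT_STARTS = (
        np.full(7, 1.0 / 7.0),                          # uniform
        np.array([7.0, 6, 5, 4, 3, 2, 1]) / 28.0,      # linear decay
        0.5 ** np.arange(7) / (0.5 ** np.arange(7)).sum(),  # geometric
        np.array([1.0, 1, 1, 0, 0, 0, 0]) / 3.0,       # first-3-days block
    )

    def _laplace_criterion(self, res: MGAMResults) -> float:
        """Laplace approximation of the marginal log-likelihood,
        log p(y|b̂) + log p(b̂) − ½ log|W + Σ_b⁻¹| (up to constants shared
        by all candidates), minus the lag-smoothness penalty; used only to
        rank multi-start fits."""
        from .lags import LAG_SMOOTHNESS, second_difference_matrix

        ar_params = res.ar_params
        D = second_difference_matrix()
        wv = res.lag_weights.w
        ll = res.loglik_conditional - LAG_SMOOTHNESS * float(
            (D @ wv) @ (D @ wv)
        )
        if ar_params.p == 0 or ar_params.sigma2 <= _SIGMA2_FLOOR:
            return ll
        n = res.frame.n
        Q = ar_mod.precision(ar_params, n)
        b = res.latent_states
        ll -= 0.5 * float(b @ (Q @ b))
        # log|Σ_b| = log|Γ_p| + (n−p) log σ²
        p = ar_params.p
        gam = ar_mod.autocovariances(ar_params.phi, ar_params.sigma2, p - 1)
        from scipy import linalg as slinalg

        sign, logdet_gp = np.linalg.slogdet(slinalg.toeplitz(gam[:p]))
        ll -= 0.5 * (logdet_gp + (n - p) * np.log(ar_params.sigma2))
        A = (diags(res.mu) + Q).tocsc()
        lu = splu(A)
        logdet_a = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        ll -= 0.5 * logdet_a
        return float(ll)

    def _update_weights(self, theta, design: Design, z, W,
                        ar_params: ArParams, max_steps: int = 30):
        """Quasi-Newton steps for the softmax lag-weight parameters on the
        profiled working GLS objective.

        The latent path is integrated out rather than held fixed: with the
        working response z and V = W⁻¹ + Σ_b, the criterion is
        ½ (z − Xβ)ᵀ V⁻¹ (z − Xβ) with β profiled by GLS.  Holding b fixed
        instead would let the latent absorb part of the temperature signal
        and shrink the weights toward their starting point.  V⁻¹ is applied
        through the banded factorisation of (W + Q).  Temperature-spline
        knots are held fixed during the line searches and refreshed at the
        accepted point.
        """
        frame = self.frame
        no_latent = ar_params.p == 0 or ar_params.sigma2 <= _SIGMA2_FLOOR
        if no_latent:
            from .gam import profile_weight_step

            theta = profile_weight_step(
                frame, theta, design.temp_basis, offset=0.0,
                maxiter=max_steps,
            )
            weights = LagWeights.from_free(theta)
            return theta, weights, frame.design(weights)

        from .lags import LAG_SMOOTHNESS, second_difference_matrix

        lam = LAG_SMOOTHNESS
        DtD = second_difference_matrix().T @ second_difference_matrix()
        Q = ar_mod.precision(ar_params, frame.n)
        A = (diags(W) + Q).tocsc()
        solver = splu(A)

        def v_inv(u):
            if u.ndim == 1:
                return W * u - W * solver.solve(W * u)
            return W[:, None] * u - W[:, None] * solver.solve(W[:, None] * u)

        def obj_and_grad(th):
            w = LagWeights.from_free(th)
            d = frame.design(w, temp_basis=design.temp_basis,
                             refresh_knots=False)
            X = d.X
            ViX = v_inv(X)
            Viz = v_inv(z)
            beta = np.linalg.solve(X.T @ ViX, X.T @ Viz)
            r = z - X @ beta
            Vr = v_inv(r)
            obj = 0.5 * float(r @ Vr)
            bt = beta[d.block("temp")]
            if d.temp_basis is None:
                slope = np.full(frame.n, bt[0])
            else:
                slope = d.temp_basis.derivative(d.exposure_weighted) @ bt
            g_w = -frame.L.T @ (Vr * slope)
            wv = w.w
            J = wv[:, None] * (np.eye(len(wv))[:, 1:] - wv[None, 1:])
            obj += lam * float(wv @ DtD @ wv)
            return obj, g_w @ J + 2.0 * lam * (DtD @ wv) @ J

        opt = optimize.minimize(
            obj_and_grad, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": max_steps, "ftol": 1e-13, "gtol": 1e-9},
        )
        theta = opt.x
        weights = LagWeights.from_free(theta)
        design = frame.design(weights)  # refresh knots at new weights
        return theta, weights, design


def fit_mgam(
    exposure,
    counts,
    spec: ModelSpec | None = None,
    ar_order: int = 2,
    weights: LagWeights | None = None,
    estimate_weights: bool = False,
    **fit_kw,
) -> MGAMResults:
    """Convenience wrapper: build an :class:`MGAM` and fit it."""
    model = MGAM(exposure, counts, spec=spec, ar_order=ar_order,
                 weights=weights)
    return model.fit(estimate_weights=estimate_weights, **fit_kw)
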