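"""Model persistence: a fitted MGAM as a single versioned JSON document.

The dump carries everything prediction needs — coefficients, lag weights,
AR parameters, the last latent states, spline knots and centering
constants — so `fit → diagnose → effects → forecast` compose across
processes and a reloaded model predicts bit-identically (the spline
transform is reconstructed deterministically from the stored knots).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ar import ArParams
from .design import ModelSpec
from .forecast import ForecastResult, propagate_latent
from .io import ExposureSeries
from .lags import LagWeights, N_LAGS, lag_matrix, weighted_exposure
from .splines import NaturalSplineBasis, basis_from_knots

SCHEMA = "mgam-model/1"


def _basis_state(basis: NaturalSplineBasis | None) -> dict | None:
    if basis is None:
        return None
    return {
        "boundary": [float(v) for v in basis.boundary_knots],
        "interior": [float(v) for v in basis.interior_knots],
        "center": [float(v) for v in basis._center],
    }


def _basis_load(state: dict | None) -> NaturalSplineBasis | None:
    if state is None:
        return None
    return basis_from_knots(state["boundary"], state["interior"],
                            center=state["center"])


def model_state(res) -> dict:
    """JSON-serialisable state of a fitted MGAM (or GAM via p = 0)."""
    spec = res.spec
    frame = res.frame
    ar = getattr(res, "ar_params", ArParams(0, np.zeros(0), 0.0))
    latent = getattr(res, "latent_states", np.zeros(frame.n))
    d = res.design
    state = {
        "schema": SCHEMA,
        "spec": {
            "df_time": spec.df_time,
            "df_temp": spec.df_temp,
            "df_pm10": spec.df_pm10,
            "include_pm10": spec.include_pm10,
            "include_rh": spec.include_rh,
            "include_so2": spec.include_so2,
            "include_no2": spec.include_no2,
            "include_weekday": spec.include_weekday,
            "lag_includes_same_day": spec.lag_includes_same_day,
        },
        "param_names": list(res.params.index),
        "params": [float(v) for v in res.params.to_numpy()],
        "lag_weights": [float(v) for v in d.weights.w],
        "ar": {"p": ar.p, "phi": [float(v) for v in ar.phi],
               "sigma2": float(ar.sigma2)},
        "latent_tail": [float(v) for v in latent[-max(ar.p, 1):]],
        "origin": str(frame.origin.date()),
        "train_end": str(frame.dates[-1].date()),
        "time_basis": _basis_state(frame.time_basis),
        "temp_basis": _basis_state(d.temp_basis),
        "temp_linear_center": (
            float(np.mean(frame.L @ d.weights.w))
            if d.temp_basis is None else None
        ),
        "pm10_basis": _basis_state(frame.pm10_basis),
        "linear_centers": {k: float(v)
                           for k, v in frame.linear_centers.items()},
        "temp_cov": np.asarray(res.block_cov("temp")).tolist(),
        "temp_range": [float(np.min(d.exposure_weighted)),
                       float(np.max(d.exposure_weighted))],
    }
    return state


def save_model(res, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_state(res), fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass
class ModelArtifact:
    """A reloaded fitted model, sufficient for prediction and effect
    curves without the training data."""

    spec: ModelSpec
    params: pd.Series
    lag_weights: LagWeights
    ar_params: ArParams
    latent_tail: np.ndarray
    origin: pd.Timestamp
    train_end: pd.Timestamp
    time_basis: NaturalSplineBasis
    temp_basis: NaturalSplineBasis | None
    temp_linear_center: float | None
    pm10_basis: NaturalSplineBasis | None
    linear_centers: dict
    temp_cov: np.ndarray = None
    temp_range: tuple = None

    @classmethod
    def from_state(cls, state: dict) -> "ModelArtifact":
        if state.get("schema") != SCHEMA:
            raise ValueError(f"unsupported model schema {state.get('schema')!r}")
        sp = dict(state["spec"])
        return cls(
            spec=ModelSpec(**sp),
            params=pd.Series(state["params"], index=state["param_names"]),
            lag_weights=LagWeights(np.asarray(state["lag_weights"])),
            ar_params=ArParams(state["ar"]["p"],
                               np.asarray(state["ar"]["phi"]),
                               state["ar"]["sigma2"]),
            latent_tail=np.asarray(state["latent_tail"], dtype=float),
            origin=pd.Timestamp(state["origin"]),
            train_end=pd.Timestamp(state["train_end"]),
            time_basis=_basis_load(state["time_basis"]),
            temp_basis=_basis_load(state["temp_basis"]),
            temp_linear_center=state.get("temp_linear_center"),
            pm10_basis=_basis_load(state.get("pm10_basis")),
            linear_centers=dict(state.get("linear_centers", {})),
            temp_cov=np.asarray(state["temp_cov"], dtype=float),
            temp_range=tuple(state["temp_range"]),
        )

    def temperature_effect(self, n_grid: int = 200):
        from .effects import curve_from_coefficients

        coef = self.params[[n for n in self.params.index
                            if n.startswith("temp")]].to_numpy()
        if self.temp_basis is None:
            center = self.temp_linear_center
            basis_fn = lambda x: (np.asarray(x, float) - center)[:, None]  # noqa: E731
        else:
            basis_fn = self.temp_basis.design
        return curve_from_coefficients(
            basis_fn, coef, self.temp_cov,
            self.temp_range[0], self.temp_range[1], n_grid=n_grid,
        )

    def fixed_design(self, exposure: ExposureSeries,
                     dates: pd.DatetimeIndex) -> np.ndarray:
        """Fixed-effects design at new dates (column order as in training)."""
        from .design import ModelFrame

        dates = pd.DatetimeIndex(dates)
        values = exposure.data["tmean"].to_numpy(dtype=float)
        if self.spec.lag_includes_same_day:
            L_all, _ = lag_matrix(values)
            lag_dates = exposure.dates[N_LAGS - 1:]
        else:
            L_all, _ = lag_matrix(values[:-1])
            lag_dates = exposure.dates[N_LAGS:]
        idx = pd.DatetimeIndex(lag_dates).get_indexer(dates)
        if np.any(idx < 0):
            missing = dates[idx < 0][0].date()
            raise ValueError(
                f"exposure does not cover {missing} (lag lead-in included)")
        t_tilde = weighted_exposure(L_all[idx], self.lag_weights)
        n = len(dates)
        cols = [np.ones((n, 1))]
        t_vals = (dates - self.origin).days.to_numpy(dtype=float)
        cols.append(self.time_basis.design(t_vals))
        if self.temp_basis is None:
            cols.append((t_tilde - self.temp_linear_center)[:, None])
        else:
            cols.append(self.temp_basis.design(t_tilde))
        cov = exposure.data.reindex(dates)
        for name, flag in (("pm10", self.spec.include_pm10),
                           ("rh", self.spec.include_rh),
                           ("so2", self.spec.include_so2),
                           ("no2", self.spec.include_no2)):
            if not flag:
                continue
            v = cov[name].to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"covariate {name} missing on new dates")
            if name == "pm10" and self.pm10_basis is not None:
                cols.append(self.pm10_basis.design(v))
            else:
                cols.append((v - self.linear_centers[name])[:, None])
        if self.spec.include_weekday:
            cols.append(ModelFrame._weekday_dummies(dates))
        return np.column_stack(cols)

    def predict(self, exposure: ExposureSeries, dates) -> ForecastResult:
        dates = pd.DatetimeIndex(dates)
        if dates.min() <= self.train_end:
            raise ValueError(
                f"forecast dates must start after the training window "
                f"(training ends {self.train_end.date()})")
        X = self.fixed_design(exposure, dates)
        fixed = X @ self.params.to_numpy()
        offsets = (dates - self.train_end).days.to_numpy()
        horizon = int(offsets.max())
        path = propagate_latent(self.ar_params.phi, self.latent_tail,
                                horizon)
        latent = path[offsets - 1]
        mu = np.exp(np.clip(fixed + latent, -30, 30))
        return ForecastResult(dates=dates, mu=mu, latent=latent,
                              fixed_eta=fixed)


def load_model(path) -> ModelArtifact:
    with open(path) as fh:
        return ModelArtifact.from_state(json.load(fh))
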