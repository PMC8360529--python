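"""Fixed-effects design construction shared by the GAM and the mixed model.

The linear predictor on the log-rate scale is

    η_t = β_0 + NS(t, df_time) + f(T̃_t; df_temp) + pollutant terms
          + weekday contrasts

where T̃_t is the 7-day weighted-average temperature.  The first days of
the series lack a complete lag window and are dropped, so the analysis
window starts 6 (or 7, when the same day is excluded from the window) days
into the exposure series.

Continuous covariates are centered on the training window and spline
columns are centered by construction, so the intercept carries the overall
log level; centering never changes fitted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountSeries, ExposureSeries
from .lags import LagWeights, N_LAGS, lag_matrix, weighted_exposure
from .splines import NaturalSplineBasis, build_basis

WEEKDAYS = ("tue", "wed", "thu", "fri", "sat", "sun")  # contrasts vs Monday

_LINEAR = "linear"


@dataclass
class ModelSpec:
    """Degrees of freedom and covariate switches for the fixed effects.

    ``df_temp`` / ``df_pm10`` accept a positive integer (natural spline with
    that many columns) or ``"linear"``.  Humidity and the gaseous pollutants
    are supported but off by default; the default model mirrors a final
    specification with temperature, PM10 and weekday terms only.
    """

    df_time: int = 5
    df_temp: int | str = 5
    df_pm10: int | str = _LINEAR
    include_pm10: bool = True
    include_rh: bool = False
    include_so2: bool = False
    include_no2: bool = False
    include_weekday: bool = True
    lag_includes_same_day: bool = True

    def __post_init__(self):
        for name in ("df_time", "df_temp", "df_pm10"):
            v = getattr(self, name)
            if v == _LINEAR:
                if name == "df_time":
                    raise ValueError("df_time must be an integer")
                continue
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer or 'linear'")

    def replace(self, **kw) -> "ModelSpec":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class Design:
    """Evaluated design matrix with named column blocks."""

    X: np.ndarray
    names: list[str]
    blocks: dict[str, slice]
    weights: LagWeights
    temp_basis: NaturalSplineBasis | None
    exposure_weighted: np.ndarray

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def block(self, name: str) -> slice:
        return self.blocks[name]


class ModelFrame:
    """Aligned response, lag matrix and covariates on the analysis window.

    Built once per (exposure, counts, spec) triple; produces design
    matrices for any candidate lag weights, and — after fitting — designs
    for new dates (forecasting), reusing the training bases and centers.
    """

    def __init__(
        self,
        exposure: ExposureSeries,
        counts,
        spec: ModelSpec,
    ):
        self.spec = spec
        self.exposure = exposure
        y = counts.stratum() if isinstance(counts, CountSeries) else counts
        if not isinstance(y, pd.Series):
            raise TypeError("counts must be a CountSeries or a pandas Series")

        values = exposure.data["tmean"].to_numpy(dtype=float)
        self.origin = exposure.dates[0]
        if spec.lag_includes_same_day:
            L, _ = lag_matrix(values)
            dates = exposure.dates[N_LAGS - 1 :]
        else:
            L, _ = lag_matrix(values[:-1])
            dates = exposure.dates[N_LAGS:]
        self.L = L
        self.dates = pd.DatetimeIndex(dates)

        y = y.reindex(self.dates)
        if y.isna().any():
            first = self.dates[y.isna().to_numpy()][0].date()
            raise ValueError(f"counts missing on analysis window (e.g. {first})")
        self.y = y.to_numpy(dtype=float)
        if np.any(self.y < 0):
            raise ValueError("negative counts")

        self.t_values = (self.dates - self.origin).days.to_numpy(dtype=float)
        self.time_basis = build_basis(self.t_values, spec.df_time)

        cov = exposure.data.reindex(self.dates)
        self.covariates = {}
        self.linear_centers = {}
        for name, flag in (
            ("pm10", spec.include_pm10),
            ("rh", spec.include_rh),
            ("so2", spec.include_so2),
            ("no2", spec.include_no2),
        ):
            if flag:
                v = cov[name].to_numpy(dtype=float)
                self.covariates[name] = v
                self.linear_centers[name] = float(v.mean())
        self.pm10_basis = None
        if spec.include_pm10 and spec.df_pm10 != _LINEAR:
            self.pm10_basis = build_basis(self.covariates["pm10"], spec.df_pm10)

        self.weekday = self._weekday_dummies(self.dates)

    @staticmethod
    def _weekday_dummies(dates: pd.DatetimeIndex) -> np.ndarray:
        dow = dates.dayofweek.to_numpy()  # Monday = 0
        return np.column_stack([(dow == i + 1).astype(float) for i in range(6)])

    @property
    def n(self) -> int:
        return len(self.y)

    def temp_basis_for(self, weights: LagWeights) -> NaturalSplineBasis | None:
        if self.spec.df_temp == _LINEAR:
            return None
        t_tilde = weighted_exposure(self.L, weights)
        return build_basis(t_tilde, self.spec.df_temp)

    def design(
        self,
        weights: LagWeights,
        temp_basis: NaturalSplineBasis | None = None,
        refresh_knots: bool = True,
    ) -> Design:
        """Design matrix at the given lag weights.

        When ``refresh_knots`` the temperature-spline knots are recomputed
        from the weighted exposure at these weights; otherwise a previously
        built basis is reused (held fixed inside weight optimisation).
        """
        t_tilde = weighted_exposure(self.L, weights)
        cols = [np.ones(self.n)]
        names = ["intercept"]
        blocks = {"intercept": slice(0, 1)}

        def add_block(name, mat, colnames):
            start = sum(c.shape[1] if c.ndim == 2 else 1 for c in cols)
            cols.append(mat)
            names.extend(colnames)
            blocks[name] = slice(start, start + mat.shape[1])

        Bt = self.time_basis.design(self.t_values)
        add_block("time", Bt, [f"time_ns{j+1}" for j in range(Bt.shape[1])])

        if self.spec.df_temp == _LINEAR:
            col = (t_tilde - t_tilde.mean())[:, None]
            add_block("temp", col, ["temp"])
            temp_basis = None
        else:
            if temp_basis is None or refresh_knots:
                temp_basis = build_basis(t_tilde, self.spec.df_temp)
            Btemp = temp_basis.design(t_tilde)
            add_block(
                "temp", Btemp, [f"temp_ns{j+1}" for j in range(Btemp.shape[1])]
            )

        for name in ("pm10", "rh", "so2", "no2"):
            if name not in self.covariates:
                continue
            v = self.covariates[name]
            if name == "pm10" and self.pm10_basis is not None:
                Bp = self.pm10_basis.design(v)
                add_block(
                    "pm10", Bp, [f"pm10_ns{j+1}" for j in range(Bp.shape[1])]
                )
            else:
                add_block(
                    name,
                    (v - self.linear_centers[name])[:, None],
                    [name],
                )

        if self.spec.include_weekday:
            add_block("weekday", self.weekday, list(WEEKDAYS))

        X = np.column_stack(cols)
        return Design(
            X=X,
            names=names,
            blocks=blocks,
            weights=weights,
            temp_basis=temp_basis,
            exposure_weighted=t_tilde,
        )

    def design_new(
        self,
        design: Design,
        exposure: ExposureSeries,
        dates: pd.DatetimeIndex,
    ) -> Design:
        """Design for new dates using the training bases and centers.

        ``exposure`` must cover the requested dates plus the lag lead-in.
        The time spline extrapolates linearly beyond its training boundary
        (natural-spline property).
        """
        dates = pd.DatetimeIndex(dates)
        values = exposure.data["tmean"].to_numpy(dtype=float)
        if self.spec.lag_includes_same_day:
            L_all, _ = lag_matrix(values)
            lag_dates = exposure.dates[N_LAGS - 1 :]
        else:
            L_all, _ = lag_matrix(values[:-1])
            lag_dates = exposure.dates[N_LAGS:]
        lag_dates = pd.DatetimeIndex(lag_dates)
        idx = lag_dates.get_indexer(dates)
        if np.any(idx < 0):
            missing = dates[idx < 0][0].date()
            raise ValueError(
                f"exposure does not cover {missing} (lag lead-in included)"
            )
        L = L_all[idx]
        t_tilde = weighted_exposure(L, design.weights)
        n = len(dates)
        t_vals = (dates - self.origin).days.to_numpy(dtype=float)

        cols = [np.ones(n)]
        cols.append(self.time_basis.design(t_vals))
        if self.spec.df_temp == _LINEAR:
            center = self.L @ design.weights.w
            cols.append((t_tilde - center.mean())[:, None])
        else:
            cols.append(design.temp_basis.design(t_tilde))
        cov = exposure.data.reindex(dates)
        for name in ("pm10", "rh", "so2", "no2"):
            if name not in self.covariates:
                continue
            v = cov[name].to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"covariate {name} missing on forecast window")
            if name == "pm10" and self.pm10_basis is not None:
                cols.append(self.pm10_basis.design(v))
            else:
                cols.append((v - self.linear_centers[name])[:, None])
        if self.spec.include_weekday:
            cols.append(self._weekday_dummies(dates))
        X = np.column_stack(cols)
        if X.shape[1] != design.k:
            raise RuntimeError("forecast design width mismatch")
        return Design(
            X=X,
            names=design.names,
            blocks=design.blocks,
            weights=design.weights,
            temp_basis=design.temp_basis,
            exposure_weighted=t_tilde,
        )
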