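"""Temperature effect curve, change points and per-zone risk ratios.

The fitted temperature smooth f(T̃) lives on the log-rate scale; the curve
is reported centered at a reference temperature (the grid median), with
pointwise delta-method standard errors from the temperature-block
coefficient covariance.  Zone risk ratios summarise the curve per +1 °C:

    RR(zone) = exp( (f(upper) − f(lower)) / (upper − lower) ),

i.e. the exponentiated average slope across the zone, with a 95% interval
from the variance of the same linear contrast of spline coefficients.
These quantities depend only on differences of f, so they are invariant to
the choice of reference temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: minimum separation (°C) between reported change points
MIN_SEPARATION = 3.0


@dataclass
class EffectCurve:
    """Centered log-rate temperature effect with pointwise SEs."""

    grid: np.ndarray
    eta: np.ndarray
    se: np.ndarray
    reference: float
    df: int
    _basis_fn: callable = None
    _cov: np.ndarray = None
    _coef: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature": self.grid, "eta": self.eta, "se": self.se}
        )

    def contrast(self, t1: float, t0: float) -> tuple[float, float]:
        """eta(t1) − eta(t0) and its standard error."""
        c = (self._basis_fn(np.array([t1]))
             - self._basis_fn(np.array([t0])))[0]
        diff = float(c @ self._coef)
        var = float(c @ self._cov @ c)
        return diff, np.sqrt(max(var, 0.0))


def temperature_effect(fit, n_grid: int = 200) -> EffectCurve:
    """Extract the fitted temperature effect curve from a GAM/MGAM fit.

    The curve spans the observed range of the weighted exposure T̃ and is
    centered so eta(reference) = 0 at the grid median temperature.
    """
    design = fit.design
    t = design.exposure_weighted
    if design.temp_basis is not None:
        basis_fn = lambda x: design.temp_basis.design(x)  # noqa: E731
    else:  # linear temperature term
        center = t.mean()
        basis_fn = lambda x: (np.asarray(x, float) - center)[:, None]  # noqa: E731
    return curve_from_coefficients(
        basis_fn, fit.block_params("temp"), fit.block_cov("temp"),
        float(t.min()), float(t.max()), n_grid=n_grid,
    )


def curve_from_coefficients(basis_fn, coef, cov, t_min: float,
                            t_max: float, n_grid: int = 200) -> EffectCurve:
    """Centered effect curve with delta-method SEs from a coefficient
    block and its covariance."""
    coef = np.asarray(coef, dtype=float)
    cov = np.asarray(cov, dtype=float)
    grid = np.linspace(t_min, t_max, n_grid)
    B = basis_fn(grid)
    # reference = central grid point, so eta(reference) is exactly zero
    reference = float(grid[(len(grid) - 1) // 2])
    Bref = basis_fn(np.array([reference]))
    C = B - Bref
    eta = C @ coef
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", C, cov, C), 0.0, None))
    return EffectCurve(
        grid=grid, eta=eta, se=se, reference=reference,
        df=len(coef), _basis_fn=basis_fn, _cov=cov, _coef=coef,
    )


def change_points(curve: EffectCurve,
                  min_separation: float = MIN_SEPARATION) -> list[float]:
    """Temperatures where the slope of the effect curve changes sign.

    Detected as sign changes of centered finite differences on the dense
    grid, de-duplicated to a minimum separation (default 3 °C) to suppress
    numerical wiggle, rounded to the nearest 1 °C and capped at df − 1
    points.  A strictly monotone curve has none.
    """
    g, e = curve.grid, curve.eta
    slope = np.gradient(e, g)
    signs = np.sign(slope)
    nz = signs != 0
    pts = []
    idx = np.flatnonzero(nz)
    prev_sign = None
    for i in idx:
        s = signs[i]
        if prev_sign is not None and s != prev_sign:
            t_cp = float(g[i])
            if not pts or t_cp - pts[-1] >= min_separation:
                pts.append(t_cp)
        prev_sign = s
    pts = [float(round(t)) for t in pts]
    max_pts = max(curve.df - 1, 0)
    return pts[:max_pts]


@dataclass
class ZoneRiskRatio:
    """Risk ratio per +1 °C within a temperature zone."""

    zone: tuple[float, float]
    rr: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


def zone_risk_ratios(curve: EffectCurve, boundaries,
                     level: float = 0.95) -> list[ZoneRiskRatio]:
    """Per-zone risk ratios from the effect curve.

    ``boundaries`` are interior cut temperatures (°C); zones run from the
    curve minimum through each boundary to the curve maximum.  Each zone
    must span at least two grid steps.
    """
    from scipy import stats

    g = curve.grid
    cuts = sorted(float(b) for b in boundaries)
    for b in cuts:
        if not (g[0] < b < g[-1]):
            raise ValueError(f"boundary {b} outside the curve range")
    edges = [float(g[0])] + cuts + [float(g[-1])]
    step = g[1] - g[0]
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < 2 * step:
            raise ValueError(f"zone ({lo}, {hi}) narrower than 2 grid steps")
        diff, se = curve.contrast(hi, lo)
        slope = diff / (hi - lo)
        slope_se = se / (hi - lo)
        out.append(
            ZoneRiskRatio(
                zone=(lo, hi),
                rr=float(np.exp(slope)),
                ci_low=float(np.exp(slope - zcrit * slope_se)),
                ci_high=float(np.exp(slope + zcrit * slope_se)),
            )
        )
    return out
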