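"""Degree-of-freedom selection for the time and covariate smooths.

Two procedures are implemented:

* **Seasonal-pattern rule for the time spline** (``select_df_time``).  The
  time smooth exists to soak up slow unmeasured confounding; give it too
  little flexibility and seasonal confounding leaks into the temperature
  curve, give it too much and it swallows the temperature signal itself
  (over-fitting: the estimated temperature effect flattens and loses
  significance).  The rule fits the GAM over a grid of candidate df, and
  for each candidate records (i) the amplitude A = max−min of the fitted
  temperature curve on the log scale and (ii) the Wald p-value of the
  temperature block.  Selected is the smallest candidate whose temperature
  block is significant (p < 0.05) and whose amplitude does not collapse —
  drop by more than half — at the next larger candidate.  The full
  per-candidate report is returned so the choice can be audited or
  overridden.

* **AIC grid search for the covariate smooths** (``select_df_aic``).  With
  the time df fixed, candidate df values for the temperature (and
  optionally PM10) splines are scored by AIC; ties go to the smaller df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .design import ModelSpec
from .gam import GAMResults, PoissonGAM
from .lags import LagWeights

AMPLITUDE_DROP = 0.5
SIGNIFICANCE = 0.05


class SelectionError(RuntimeError):
    pass


@dataclass
class DfTimeReport:
    """Per-candidate amplitudes/p-values and the selected time df."""

    selected: int
    table: pd.DataFrame
    overfit_flagged: list[int] = field(default_factory=list)


def temperature_amplitude(fit: GAMResults) -> float:
    """max − min of the fitted temperature effect on the log scale."""
    curve = fit.temperature_effect()
    return float(np.max(curve.eta) - np.min(curve.eta))


def select_df_time(
    exposure,
    counts,
    spec_template: ModelSpec | None = None,
    grid=None,
    weights: LagWeights | None = None,
) -> DfTimeReport:
    """Choose the time-spline df by the seasonal-pattern criterion."""
    spec_template = spec_template or ModelSpec()
    grid = sorted(grid if grid is not None else range(2, 13))
    rows = []
    for df_t in grid:
        spec = spec_template.replace(df_time=int(df_t))
        fit = PoissonGAM(exposure, counts, spec=spec, weights=weights).fit()
        amp = temperature_amplitude(fit)
        stat, dfw, p = fit.wald_test("temp")
        rows.append(
            {"df_time": int(df_t), "amplitude": amp, "wald_chi2": stat,
             "p_value": p, "aic": fit.aic}
        )
    table = pd.DataFrame(rows).set_index("df_time")

    amps = table["amplitude"].to_numpy()
    pvals = table["p_value"].to_numpy()
    overfit = [
        int(table.index[i])
        for i in range(len(grid))
        if pvals[i] >= SIGNIFICANCE
        or (amps[i] < AMPLITUDE_DROP * np.max(amps[: i + 1]))
    ]
    selected = None
    for i, df_t in enumerate(table.index):
        if pvals[i] >= SIGNIFICANCE:
            continue
        if i + 1 < len(amps) and amps[i + 1] < AMPLITUDE_DROP * amps[i]:
            continue
        selected = int(df_t)
        break
    if selected is None:
        raise SelectionError(
            "no candidate time df keeps a significant, stable temperature "
            "effect; extend the grid"
        )
    return DfTimeReport(selected=selected, table=table,
                        overfit_flagged=overfit)


@dataclass
class DfAicReport:
    selected: dict
    table: pd.DataFrame


def select_df_aic(
    exposure,
    counts,
    spec_template: ModelSpec | None = None,
    df_time: int | None = None,
    df_temp_grid=None,
    df_pm10_grid=None,
    weights: LagWeights | None = None,
) -> DfAicReport:
    """Grid-search covariate-spline df by AIC (ties broken to smaller df).

    ``df_temp_grid``/``df_pm10_grid`` are iterables of positive integers or
    the string ``"linear"``; a ``None`` grid keeps that term at the
    template's setting.
    """
    spec_template = spec_template or ModelSpec()
    if df_time is not None:
        spec_template = spec_template.replace(df_time=int(df_time))
    temp_grid = list(df_temp_grid) if df_temp_grid is not None else [
        spec_template.df_temp
    ]
    pm10_grid = list(df_pm10_grid) if df_pm10_grid is not None else [
        spec_template.df_pm10
    ]

    def complexity(v):
        return 1 if v == "linear" else int(v)

    rows = []
    best = None
    for df_temp, df_pm10 in product(temp_grid, pm10_grid):
        spec = spec_template.replace(df_temp=df_temp, df_pm10=df_pm10)
        fit = PoissonGAM(exposure, counts, spec=spec, weights=weights).fit()
        rows.append({"df_temp": df_temp, "df_pm10": df_pm10, "aic": fit.aic,
                     "deviance": fit.deviance})
        key = (fit.aic, complexity(df_temp) + complexity(df_pm10))
        if best is None or key < best[0]:
            best = (key, {"df_temp": df_temp, "df_pm10": df_pm10})
    table = pd.DataFrame(rows)
    return DfAicReport(selected=best[1], table=table)
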