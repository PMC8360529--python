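"""Reading, validation and description of daily exposure and count series.

The package works on two aligned daily tables: an exposure table with mean
ambient temperature (°C), relative humidity (%) and pollutant concentrations
(μg/m³), and an event-count table with non-negative daily case counts per
stratum (e.g. sex).  Both live on a contiguous calendar-day grid; lag
construction and the latent autoregressive process both rely on that grid,
so gaps are either interpolated (short ones, covariates only) or rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXPOSURE_COLUMNS = ("tmean", "rh", "so2", "no2", "pm10")

#: longest covariate gap (days) bridged by linear interpolation
MAX_INTERP_GAP = 3


class SeriesValidationError(ValueError):
    """Raised when an input table violates a series invariant."""


@dataclass
class ExposureSeries:
    """Daily meteorology and pollutants on a contiguous date grid.

    Attributes
    ----------
    data : pandas.DataFrame
        Indexed by a daily ``DatetimeIndex`` with columns
        ``tmean`` (°C), ``rh`` (%), ``so2``, ``no2``, ``pm10`` (μg/m³).
    interpolated : pandas.DataFrame
        Boolean mask marking values filled by short-gap interpolation.
    """

    data: pd.DataFrame
    interpolated: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        self.data = _validate_exposure_frame(self.data)
        if self.interpolated is None:
            self.interpolated = pd.DataFrame(
                False, index=self.data.index, columns=list(EXPOSURE_COLUMNS)
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)


@dataclass
class CountSeries:
    """Daily non-negative integer event counts, optionally stratified.

    ``data`` is a long-format frame with columns ``date``, ``stratum``,
    ``count``; one row per (date, stratum).
    """

    data: pd.DataFrame

    def __post_init__(self):
        self.data = _validate_count_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def strata(self) -> list:
        return sorted(self.data["stratum"].unique())

    def stratum(self, label=None) -> pd.Series:
        """Return one stratum as a date-indexed count series."""
        if label is None:
            labels = self.strata
            if len(labels) != 1:
                raise ValueError(
                    f"stratum label required; available: {labels}"
                )
            label = labels[0]
        sub = self.data[self.data["stratum"] == label]
        if sub.empty:
            raise KeyError(f"no such stratum: {label!r}")
        s = pd.Series(
            sub["count"].to_numpy(), index=pd.DatetimeIndex(sub["date"]),
            name=str(label),
        )
        return s.sort_index()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def _validate_exposure_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if not isinstance(df.index, pd.DatetimeIndex):
        raise SeriesValidationError("exposure frame must have a DatetimeIndex")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0].date()
        raise SeriesValidationError(f"duplicate date: {dup}")
    df = df.sort_index()
    step = np.diff(df.index.to_julian_date())
    if len(df) > 1 and not np.all(step == 1.0):
        gap_at = df.index[int(np.argmax(step != 1.0))].date()
        raise SeriesValidationError(
            f"dates are not a contiguous daily grid (gap after {gap_at})"
        )
    missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
    if missing:
        raise SeriesValidationError(f"missing exposure columns: {missing}")
    df = df[list(EXPOSURE_COLUMNS)].astype(float)
    rh = df["rh"].dropna()
    if ((rh < 0) | (rh > 100)).any():
        raise SeriesValidationError("relative humidity outside [0, 100]")
    for c in ("so2", "no2", "pm10"):
        v = df[c].dropna()
        if (v < 0).any():
            raise SeriesValidationError(f"negative {c} concentration")
    return df


def _validate_count_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in ("date", "stratum", "count"):
        if c not in df.columns:
            raise SeriesValidationError(f"missing count column: {c}")
    df["date"] = pd.DatetimeIndex(pd.to_datetime(df["date"])).normalize()
    counts = df["count"].to_numpy()
    as_float = np.asarray(counts, dtype=float)
    if not np.all(np.isfinite(as_float)):
        raise SeriesValidationError("non-finite count value")
    if np.any(as_float < 0):
        bad = df.loc[as_float < 0, "date"].iloc[0].date()
        raise SeriesValidationError(f"negative count on {bad}")
    if np.any(as_float != np.round(as_float)):
        bad = df.loc[as_float != np.round(as_float), "date"].iloc[0].date()
        raise SeriesValidationError(f"non-integer count on {bad}")
    df["count"] = as_float.astype(int)
    if df.duplicated(["date", "stratum"]).any():
        row = df[df.duplicated(["date", "stratum"])].iloc[0]
        raise SeriesValidationError(
            f"duplicate record for ({row['date'].date()}, {row['stratum']})"
        )
    return df.sort_values(["stratum", "date"]).reset_index(drop=True)


def read_exposure_csv(path, column_map: dict | None = None) -> ExposureSeries:
    """Read a daily meteorological/pollutant CSV.

    Parameters
    ----------
    path : str or file
        CSV with a header row naming the date column and the five exposure
        variables.
    column_map : dict, optional
        Mapping from canonical names (``date``, ``tmean``, ``rh``, ``so2``,
        ``no2``, ``pm10``) to the column names used in the file, so any CSV
        dialect can be adapted without code changes.

    Short covariate gaps (≤ 3 consecutive missing days) are bridged by
    linear interpolation and flagged; longer gaps are an error because lag
    construction needs a contiguous grid.
    """
    raw = pd.read_csv(path)
    column_map = column_map or {}
    rename = {column_map.get(k, k): k for k in ("date",) + EXPOSURE_COLUMNS}
    present = [c for c in rename if c in raw.columns]
    raw = raw[present].rename(columns={c: rename[c] for c in present})
    if "date" not in raw.columns:
        raise SeriesValidationError(
            f"no date column found (looked for {column_map.get('date', 'date')!r})"
        )
    missing = [c for c in EXPOSURE_COLUMNS if c not in raw.columns]
    if missing:
        raise SeriesValidationError(f"missing exposure columns: {missing}")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(raw["date"])).normalize()
    except (ValueError, TypeError) as exc:
        raise SeriesValidationError(f"unparseable date column: {exc}") from exc
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0].date()
        raise SeriesValidationError(f"duplicate date: {dup}")
    for c in EXPOSURE_COLUMNS:
        coerced = pd.to_numeric(raw[c], errors="coerce")
        bad = coerced.isna() & raw[c].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise SeriesValidationError(
                f"unparseable value in column {c!r}, row {i + 2} "
                f"(date {dates[i].date()}): {raw[c].iloc[i]!r}"
            )
        raw[c] = coerced
    df = raw.set_index(dates)[list(EXPOSURE_COLUMNS)].sort_index()

    # reindex onto the full daily grid, then bridge short gaps
    full = pd.date_range(df.index[0], df.index[-1], freq="D")
    df = df.reindex(full)
    filled = df.isna()
    if filled.to_numpy().any():
        for c in EXPOSURE_COLUMNS:
            na = df[c].isna()
            if not na.any():
                continue
            runs = _na_run_lengths(na.to_numpy())
            if runs.max(initial=0) > MAX_INTERP_GAP:
                raise SeriesValidationError(
                    f"column {c!r} has a missing run longer than "
                    f"{MAX_INTERP_GAP} days"
                )
            df[c] = df[c].interpolate(method="linear", limit_area="inside")
            if df[c].isna().any():
                raise SeriesValidationError(
                    f"column {c!r} missing at the series boundary"
                )
    series = ExposureSeries(df)
    series.interpolated = filled[list(EXPOSURE_COLUMNS)]
    return series


def _na_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of consecutive True runs in a boolean array."""
    if not mask.any():
        return np.array([], dtype=int)
    padded = np.r_[0, mask.astype(int), 0]
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return ends - starts


def read_count_csv(path, column_map: dict | None = None) -> CountSeries:
    """Read a daily event-count CSV (long format: date, stratum, count)."""
    raw = pd.read_csv(path)
    column_map = column_map or {}
    rename = {column_map.get(k, k): k for k in ("date", "stratum", "count")}
    present = [c for c in rename if c in raw.columns]
    raw = raw[present].rename(columns={c: rename[c] for c in present})
    if "stratum" not in raw.columns:
        raw["stratum"] = "all"
    return CountSeries(raw)


SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

SEASONS = ("spring", "summer", "autumn", "winter")


def season_of(date) -> str:
    """Calendar season: spring Mar–May, summer Jun–Aug, autumn Sep–Nov,
    winter Dec–Feb."""
    return SEASON_OF_MONTH[pd.Timestamp(date).month]


def describe_by_season(series: pd.Series) -> pd.DataFrame:
    """Mean, sample SD, min and max per season plus a whole-year row.

    ``series`` must be indexed by dates.  Groups are defined purely by
    calendar month.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        series = pd.Series(
            series.to_numpy(), index=pd.DatetimeIndex(series.index)
        )
    labels = pd.Series(
        [SEASON_OF_MONTH[m] for m in series.index.month], index=series.index
    )
    rows = {}
    for season in SEASONS:
        grp = series[labels == season]
        if grp.empty:
            raise SeriesValidationError(f"no observations in {season}")
        rows[season] = _describe(grp)
    rows["whole_year"] = _describe(series)
    return pd.DataFrame.from_dict(rows, orient="index")


def _describe(s: pd.Series) -> dict:
    v = s.dropna().to_numpy(dtype=float)
    if v.size == 0:
        raise SeriesValidationError("empty group")
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }


def correlate(a, b, method: str = "pearson") -> float:
    """Pearson or Spearman correlation between two aligned series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d series")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values not allowed")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def annual_totals(
    counts: CountSeries | pd.Series,
    population: dict[int, float] | None = None,
    stratum=None,
) -> pd.DataFrame:
    """Yearly event totals and crude rates per 1,000 population.

    ``population`` maps calendar year to population size (same unit as the
    counts; rates come out per 1,000 of that unit).  Incomplete calendar
    years are kept but flagged with a warning.
    """
    if isinstance(counts, CountSeries):
        s = counts.stratum(stratum)
    else:
        s = counts
    years = s.index.year
    out = []
    for year in np.unique(years):
        sub = s[years == year]
        n_days = 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365
        if len(sub) < n_days:
            warnings.warn(
                f"year {year} is incomplete ({len(sub)}/{n_days} days)",
                UserWarning, stacklevel=2,
            )
        total = int(sub.sum())
        row = {"year": int(year), "count": total}
        if population is not None and int(year) in population:
            row["rate_per_1000"] = total / population[int(year)] * 1000.0
        out.append(row)
    return pd.DataFrame(out).set_index("year")
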