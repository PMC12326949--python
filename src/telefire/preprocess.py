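"""Monthly time-series preprocessing for the attribution pipeline.

Per grid cell the pipeline (i) finds the fire-season peak — the three
consecutive calendar months with the highest accumulated burned area,
searched circularly so Southern-Hemisphere DJF-type seasons are found;
(ii) removes the linear trend over the whole record; (iii) subtracts the
long-term mean of each calendar month (monthly-climatology anomalies); and
(iv) builds the per-cell regression sample frame pairing fire-season
response values with predictors lagged 0..24 months backward in time, so a
predictor always coincides with or precedes the fire month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyGrid",
    "IndexSeries",
    "FireSeason",
    "CellSampleSet",
    "detect_fire_season",
    "detrend",
    "monthly_anomaly",
    "build_samples",
]

SEASON_LENGTH = 3  # fire-season window length in months (fixed)


def _monthly_period_index(time_axis) -> pd.PeriodIndex:
    idx = pd.PeriodIndex(time_axis, freq="M")
    if len(idx) > 1:
        steps = np.diff(idx.asi8)
        if not np.all(steps == 1):
            gaps = idx[1:][steps != 1]
            raise ValueError(f"time axis not consecutive monthly; gaps before {list(gaps[:3])}")
    return idx


@dataclass
class MonthlyGrid:
    """A (time, lat, lon) cube of one monthly variable.

    ``values`` holds NaN at masked (non-burnable) cells for every time step.
    ``variable_role`` is one of {"BA", "FRP", "weather-mediator",
    "fuel-mediator", "other"}.
    """

    values: np.ndarray
    time: pd.PeriodIndex
    mask: np.ndarray
    name: str = ""
    units: str = ""
    variable_role: str = "other"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time = _monthly_period_index(self.time)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        if self.values.shape[0] != len(self.time):
            raise ValueError("time axis length mismatch")
        if self.values.shape[1:] != self.mask.shape:
            raise ValueError("mask shape mismatch")

    @property
    def n_months(self) -> int:
        return len(self.time)

    def cell_series(self, cell) -> np.ndarray:
        i, j = cell
        return self.values[:, i, j]


@dataclass
class IndexSeries:
    """One teleconnection-mode index as a monthly scalar series."""

    values: np.ndarray
    time: pd.PeriodIndex
    name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.time = _monthly_period_index(self.time)
        if len(self.values) != len(self.time):
            raise ValueError("index series / time axis length mismatch")


@dataclass(frozen=True)
class FireSeason:
    """Start calendar month (1..12) of the 3-month fire-season window.

    The window may wrap December->February; ``months`` lists the calendar
    months it covers.
    """

    start_month: int

    @property
    def months(self) -> tuple[int, int, int]:
        return tuple((self.start_month - 1 + k) % 12 + 1 for k in range(SEASON_LENGTH))


def detect_fire_season(ba: np.ndarray, time: pd.PeriodIndex) -> FireSeason | None:
    """Three consecutive calendar months with highest accumulated BA.

    The 12-month climatology of summed BA is scanned with circular 3-month
    windows; ties break toward the earliest calendar start month.  Returns
    None when the cell has no burned area at all (no fire season).
    """
    ba = np.asarray(ba, dtype=float)
    clim = np.zeros(12)
    months = np.asarray(time.month)
    for m in range(1, 13):
        sel = ba[months == m]
        sel = sel[np.isfinite(sel)]
        clim[m - 1] = sel.sum()
    if not np.any(clim > 0):
        return None
    window = np.array([clim[np.arange(s, s + SEASON_LENGTH) % 12].sum() for s in range(12)])
    return FireSeason(start_month=int(np.argmax(window)) + 1)


def detrend(series: np.ndarray) -> np.ndarray:
    """Residuals of an OLS fit of value on time index over the full record.

    NaNs are ignored in the fit and preserved in the output; an all-missing
    series maps to all-missing.
    """
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    t = np.arange(x.size, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 3:
        if ok.sum() == 0:
            return out
        out[ok] = x[ok] - np.nanmean(x)
        return out
    tm = t[ok].mean()
    xm = x[ok].mean()
    dt = t[ok] - tm
    denom = dt @ dt
    slope = (dt @ (x[ok] - xm)) / denom if denom > 0 else 0.0
    out[ok] = x[ok] - (xm + slope * dt)
    return out


def monthly_anomaly(series: np.ndarray, time: pd.PeriodIndex) -> np.ndarray:
    """Subtract the long-term mean of the corresponding calendar month."""
    x = np.asarray(series, dtype=float)
    time = pd.PeriodIndex(time, freq="M")
    months = np.asarray(time.month)
    present = set(np.unique(months))
    missing = sorted(set(range(1, 13)) - present)
    if missing:
        raise ValueError(f"calendar months absent from time axis: {missing}")
    out = np.full_like(x, np.nan)
    for m in range(1, 13):
        sel = months == m
        vals = x[sel]
        ok = np.isfinite(vals)
        if ok.any():
            out[sel] = vals - vals[ok].mean()
    return out


def preprocess_series(series: np.ndarray, time: pd.PeriodIndex, *, anomaly: bool = True) -> np.ndarray:
    """Remove the linear trend and (for mediators and BA) the monthly climatology.

    Teleconnection indices are detrended only (``anomaly=False``).  For
    mediators and BA the trend and the twelve calendar-month means are
    removed *jointly* (one least-squares projection on trend plus month
    indicators): sequentially detrending and then subtracting month means
    leaves a small residual trend because the two projections do not
    commute, while the joint projection — the limit of alternating the two
    steps — leaves residuals with exactly zero trend and zero per-month
    means.
    """
    if not anomaly:
        return detrend(series)
    x = np.asarray(series, dtype=float)
    time = pd.PeriodIndex(time, freq="M")
    months = np.asarray(time.month)
    missing = sorted(set(range(1, 13)) - set(np.unique(months)))
    if missing:
        raise ValueError(f"calendar months absent from time axis: {missing}")
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    if ok.sum() < 14:
        return monthly_anomaly(detrend(x), time) if ok.any() else out
    t = np.arange(x.size, dtype=float)
    D = np.zeros((x.size, 13))
    for m in range(1, 13):
        D[months == m, m - 1] = 1.0
    D[:, 12] = t - t.mean()
    beta, *_ = np.linalg.lstsq(D[ok], x[ok], rcond=None)
    out[ok] = x[ok] - D[ok] @ beta
    return out


@dataclass
class CellSampleSet:
    """Per-cell regression samples: fire-season responses x lagged predictors.

    ``lagged[t]`` is the predictor aligned to lead the response by t months;
    every lag shares the same samples (years that would require predictor
    values before the record start are dropped for *all* lags, so sample
    size — and hence R² — is comparable across lags).
    """

    response: np.ndarray
    lagged: np.ndarray  # (max_lag+1, n_samples)
    months: pd.PeriodIndex = field(repr=False)
    years: np.ndarray = field(repr=False)
    max_lag: int = 24
    insufficient: bool = False

    @property
    def n_samples(self) -> int:
        return self.response.size

    def lagged_predictor(self, t: int) -> np.ndarray:
        return self.lagged[t]

    @property
    def design(self) -> np.ndarray:
        """(n_samples, max_lag+1) matrix of lagged predictor columns."""
        return self.lagged.T


def _season_month_indices(time: pd.PeriodIndex, season: FireSeason):
    """Per-year absolute month indices of the 3 season months (may wrap)."""
    first = time[0]
    out = []
    year = first.year - 1
    last = time[-1]
    while True:
        start = pd.Period(year=year, month=season.start_month, freq="M")
        if start > last:
            break
        idx0 = start.ordinal - first.ordinal
        out.append((year, [idx0 + k for k in range(SEASON_LENGTH)]))
        year += 1
    return out


def build_samples(
    response_series: np.ndarray,
    predictor_series: np.ndarray,
    time: pd.PeriodIndex,
    season: FireSeason,
    *,
    max_lag: int = 24,
    min_samples: int = 10,
    season_aggregate: bool = False,
) -> CellSampleSet:
    """Pair fire-season response values with 0..max_lag lagged predictors.

    Parameters
    ----------
    response_series, predictor_series : arrays on the common monthly axis
        Already preprocessed (detrended / anomaly) series.
    season_aggregate : bool
        If True, the three monthly values of each fire season (and each
        lagged predictor) are averaged into one sample per year; default
        keeps the three monthly samples.
    """
    y = np.asarray(response_series, dtype=float)
    x = np.asarray(predictor_series, dtype=float)
    if y.size != x.size or y.size != len(time):
        raise ValueError("response/predictor/time length mismatch")
    n = y.size
    sel_months: list[int] = []
    sel_years: list[int] = []
    for year, idxs in _season_month_indices(time, season):
        if idxs[0] - max_lag < 0 or idxs[-1] >= n:
            continue  # drop years that any lag (or the record end) truncates
        if not all(np.isfinite(y[k]) for k in idxs):
            continue
        sel_months.extend(idxs)
        sel_years.extend([year] * SEASON_LENGTH)
    mi = np.asarray(sel_months, dtype=int)
    lag_rows = np.arange(max_lag + 1)
    if mi.size == 0:
        empty = np.zeros((max_lag + 1, 0))
        return CellSampleSet(np.zeros(0), empty, pd.PeriodIndex([], freq="M"),
                             np.zeros(0, int), max_lag, insufficient=True)
    lagged = x[mi[None, :] - lag_rows[:, None]]
    response = y[mi]
    months = time[mi]
    years = np.asarray(sel_years, dtype=int)
    if season_aggregate:
        g = years.reshape(-1, SEASON_LENGTH)
        response = response.reshape(-1, SEASON_LENGTH).mean(axis=1)
        lagged = lagged.reshape(max_lag + 1, -1, SEASON_LENGTH).mean(axis=2)
        months = months[::SEASON_LENGTH]
        years = g[:, 0]
    ss = CellSampleSet(response, lagged, months, years, max_lag)
    if ss.n_samples < min_samples:
        ss.insufficient = True
        warnings.warn(
            f"only {ss.n_samples} samples (< {min_samples}); cell flagged insufficient",
            stacklevel=2,
        )
    return ss
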