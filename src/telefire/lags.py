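"""Lagged Pearson correlation profiles between teleconnection indices and BA.

Within a hot spot, each cell contributes the Pearson correlation between its
fire-season BA anomalies and the index lagged 0..24 months; correlations
that are not significant at the 0.05 level are set to zero.  Per-lag mean
absolute (gated) correlations, normalized so the profile peaks at 1, give
the hot spot's lag distribution; the positive/negative fractions at each lag
split the absolute-correlation mass by sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CellSampleSet

__all__ = ["LagProfile", "lag_correlations", "gated_correlations", "build_lag_profile"]


@dataclass
class LagProfile:
    tcm: str
    region_id: int
    weight: np.ndarray  # per lag, in [0, 1]; max = 1 unless all-zero
    pos_frac: np.ndarray
    neg_frac: np.ndarray

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.weight.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": self.region_id, "tcm": self.tcm, "lag": self.lags,
            "weight": self.weight, "pos_frac": self.pos_frac, "neg_frac": self.neg_frac,
        })


def pearson_by_lag(samples: CellSampleSet):
    """Pearson r and two-sided p between the response and every lagged copy.

    Zero-variance vectors yield r = 0 (with a warning), p = 1.
    """
    y = samples.response
    X = samples.lagged  # (L+1, n)
    n = y.size
    if n < 3:
        return np.zeros(X.shape[0]), np.ones(X.shape[0])
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(Xc**2, axis=1))
    degenerate = (sx <= 0) | (sy <= 0) | ~np.isfinite(sx)
    if degenerate.any() and np.isfinite(sx).all():
        warnings.warn("zero-variance vector in lag correlation; r set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return r, p


def lag_correlations(samples: CellSampleSet, *, alpha: float = 0.05):
    """r(t), p(t) for t = 0..max_lag, with r gated to 0 where p > alpha."""
    r, p = pearson_by_lag(samples)
    return np.where(p < alpha, r, 0.0), p


def gated_correlations(samples: CellSampleSet, *, alpha: float = 0.05) -> np.ndarray:
    return lag_correlations(samples, alpha=alpha)[0]


def build_lag_profile(
    cell_correlations: list[np.ndarray],
    *,
    tcm: str = "",
    region_id: int = 0,
    denominator: str = "all",
) -> LagProfile:
    """Aggregate per-cell gated correlations into a normalized lag profile.

    Parameters
    ----------
    cell_correlations : list of per-cell gated r arrays (length max_lag+1)
    denominator : "all" divides the per-lag |r| sum by the number of region
        cells (cells contribute zeros where not significant); "significant"
        divides by the count of cells significant at that lag.
    """
    if denominator not in ("all", "significant"):
        raise ValueError("denominator must be 'all' or 'significant'")
    R = np.asarray(cell_correlations, dtype=float)  # (cells, lags)
    if R.ndim != 2 or R.shape[0] == 0:
        raise ValueError("need at least one cell")
    absR = np.abs(R)
    sum_abs = absR.sum(axis=0)
    if denominator == "all":
        mean_abs = sum_abs / R.shape[0]
    else:
        counts = (absR > 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_abs = np.where(counts > 0, sum_abs / np.maximum(counts, 1), 0.0)
    peak = mean_abs.max()
    weight = mean_abs / peak if peak > 0 else np.zeros_like(mean_abs)
    pos_sum = np.where(R > 0, absR, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_frac = np.where(sum_abs > 0, pos_sum / sum_abs, 0.0)
    neg_frac = np.where(sum_abs > 0, 1.0 - pos_frac, 0.0)
    return LagProfile(tcm=tcm, region_id=region_id, weight=weight,
                      pos_frac=pos_frac, neg_frac=neg_frac)


def plot_lag_profile(profile: LagProfile, ax=None):
    """Stacked-bar rendering of a lag profile (positive vs negative mass)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    lags = profile.lags
    ax.bar(lags, profile.weight * profile.pos_frac, color="#c0392b", label="positive")
    ax.bar(lags, profile.weight * profile.neg_frac,
           bottom=profile.weight * profile.pos_frac, color="#2980b9", label="negative")
    ax.set_xlabel("time lag (months)")
    ax.set_ylabel("normalized |r|")
    ax.set_title(f"{profile.tcm} — hot spot {profile.region_id}")
    ax.legend(frameon=False, fontsize=8)
    return ax
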