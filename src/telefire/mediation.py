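"""Three-step regression pathway analysis: TCM -> mediator -> burned area.

For a lag pair (i, j) with i + j <= 24, three univariate OLS regressions are
fitted on the shared fire-season sample frame:

    (1)  BA            = a1 + b1 * TCM_{i+j}       -> R1², p1
    (2)  Mediator_j    = a2 + b2 * TCM_{i+j}       -> R2², p2
    (3)  BA            = a3 + b3 * Mediator_j      -> R3², p3

Regressions 2 and 3 are run only when regression 1 is significant, and the
pathway contribution is

    contribution = R1² * R2²   if p1, p2, p3 all < 0.05, else 0.

Contributions are summed over all lag pairs and cells per (hot spot, TCM,
mediator) and compared across the weather {Tmax, ET0, VPD, Wind} and fuel
{NDVI, EVI, FPAR, SM} mediator groups (group sum and group max), yielding
dominant-mediator and dominant-group calls; the same comparison is also made
cell by cell.  R3² never enters the score — only its p-value gates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CellSampleSet
from .synthetic import FUEL_MEDIATORS, WEATHER_MEDIATORS

__all__ = [
    "PathwayFit",
    "ContributionTable",
    "pathway_fit",
    "enumerate_pathways",
    "pathway_contribution_frame",
    "aggregate_contributions",
    "per_cell_dominance",
]


@dataclass
class PathwayFit:
    tcm: str
    mediator: str
    i: int
    j: int
    a1: float = np.nan
    b1: float = np.nan
    r1_sq: float = np.nan
    p1: float = np.nan
    a2: float = np.nan
    b2: float = np.nan
    r2_sq: float = np.nan
    p2: float = np.nan
    a3: float = np.nan
    b3: float = np.nan
    r3_sq: float = np.nan
    p3: float = np.nan
    contribution: float = 0.0


def _ols(x: np.ndarray, y: np.ndarray):
    """Univariate OLS: intercept, slope, R², two-sided p of the F/t test."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) <= 0 or np.std(y) <= 0:
        warnings.warn("degenerate variance in pathway regression", stacklevel=2)
        return np.nan, np.nan, 0.0, 1.0
    res = stats.linregress(x, y)
    return res.intercept, res.slope, float(res.rvalue**2), float(res.pvalue)


def pathway_fit(
    ba: np.ndarray,
    tcm_lagged: np.ndarray,
    mediator_lagged: np.ndarray,
    *,
    tcm: str = "",
    mediator: str = "",
    i: int = 0,
    j: int = 0,
    alpha: float = 0.05,
) -> PathwayFit:
    """One lag pair: the three regressions with the sequential p1 gate.

    ``tcm_lagged`` is the index at lag i+j and ``mediator_lagged`` the
    mediator anomaly at lag j, both on the same sample frame as ``ba``.
    """
    fit = PathwayFit(tcm=tcm, mediator=mediator, i=i, j=j)
    fit.a1, fit.b1, fit.r1_sq, fit.p1 = _ols(tcm_lagged, ba)
    if fit.p1 >= alpha:
        return fit
    fit.a2, fit.b2, fit.r2_sq, fit.p2 = _ols(tcm_lagged, mediator_lagged)
    fit.a3, fit.b3, fit.r3_sq, fit.p3 = _ols(mediator_lagged, ba)
    if fit.p2 < alpha and fit.p3 < alpha:
        fit.contribution = fit.r1_sq * fit.r2_sq
    return fit


def enumerate_pathways(
    tcm_samples: CellSampleSet,
    mediator_samples: CellSampleSet,
    *,
    tcm: str = "",
    mediator: str = "",
    max_total_lag: int = 24,
    alpha: float = 0.05,
) -> list[PathwayFit]:
    """All (i, j) with i, j >= 0 and i + j <= max_total_lag, ordered by (i, j).

    Yields sum_{s=0}^{L}(s+1) fits — 325 at the default L = 24.
    """
    out = []
    for i in range(max_total_lag + 1):
        for j in range(max_total_lag + 1 - i):
            out.append(pathway_fit(
                tcm_samples.response,
                tcm_samples.lagged_predictor(i + j),
                mediator_samples.lagged_predictor(j),
                tcm=tcm, mediator=mediator, i=i, j=j, alpha=alpha,
            ))
    return out


def _corr_and_p(A: np.ndarray, B: np.ndarray):
    """Row-pairwise correlations: A (a, n), B (b, n) -> r, p of shape (a, b)."""
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(Ac**2, axis=1))
    sb = np.sqrt(np.sum(Bc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(sa, sb)
    bad = ~np.isfinite(r)
    r = np.where(bad, 0.0, np.clip(r, -1, 1))
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(bad, 1.0, p)
    return r, p


def pathway_contribution_frame(
    tcm_samples: CellSampleSet,
    mediator_samples: CellSampleSet,
    *,
    tcm: str = "",
    mediator: str = "",
    max_total_lag: int = 24,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorized contributions over every (i, j); same gates as pathway_fit.

    R1² and p1 depend only on the total lag s = i + j; R3²/p3 only on j;
    R2²/p2 on (s, j) — so three correlation tables cover all 325 pairs.
    """
    L = max_total_lag
    y = tcm_samples.response[None, :]
    T = tcm_samples.lagged[: L + 1]
    M = mediator_samples.lagged[: L + 1]
    r1, p1 = _corr_and_p(T, y)  # (L+1, 1) by total lag s
    r3, p3 = _corr_and_p(M, y)  # (L+1, 1) by j
    r2, p2 = _corr_and_p(T, M)  # (s, j)
    rows = []
    for i in range(L + 1):
        for j in range(L + 1 - i):
            s = i + j
            sig1 = p1[s, 0] < alpha
            contrib = 0.0
            if sig1 and p2[s, j] < alpha and p3[j, 0] < alpha:
                contrib = float(r1[s, 0] ** 2 * r2[s, j] ** 2)
            rows.append((tcm, mediator, i, j,
                         float(r1[s, 0] ** 2), float(p1[s, 0]),
                         float(r2[s, j] ** 2) if sig1 else np.nan,
                         float(p2[s, j]) if sig1 else np.nan,
                         float(r3[j, 0] ** 2) if sig1 else np.nan,
                         float(p3[j, 0]) if sig1 else np.nan,
                         contrib))
    return pd.DataFrame(rows, columns=[
        "tcm", "mediator", "i", "j", "r1_sq", "p1",
        "r2_sq", "p2", "r3_sq", "p3", "contribution",
    ])


@dataclass
class ContributionTable:
    """Summed pathway contributions and the derived dominance calls."""

    by_mediator: pd.DataFrame  # region_id, tcm, mediator, contribution, fraction
    by_group: pd.DataFrame  # region_id, tcm, group, group_sum, group_max
    dominance: pd.DataFrame  # region_id, tcm, dominant_mediator, dominant_group_{sum,max}, tie


def mediator_group(name: str) -> str:
    if name in WEATHER_MEDIATORS:
        return "weather"
    if name in FUEL_MEDIATORS:
        return "fuel"
    return "other"


def aggregate_contributions(fits: pd.DataFrame, *, groups: dict | None = None) -> ContributionTable:
    """Sum contributions per (region, tcm, mediator) and compare groups.

    ``fits`` needs columns region_id, tcm, mediator, contribution (typically
    the concatenated per-cell frames).  An all-TCM aggregate row (tcm="All")
    is appended per region.  Rows whose total over mediators is zero keep
    fraction = NaN and are flagged ``undefined``.
    """
    if groups is None:
        groups = {m: mediator_group(m) for m in fits["mediator"].unique()}
    base = (fits.groupby(["region_id", "tcm", "mediator"], as_index=False)["contribution"]
            .sum())
    allrows = (fits.groupby(["region_id", "mediator"], as_index=False)["contribution"]
               .sum())
    allrows.insert(1, "tcm", "All")
    by_med = pd.concat([base, allrows], ignore_index=True)
    totals = by_med.groupby(["region_id", "tcm"])["contribution"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        by_med["fraction"] = np.where(totals > 0, by_med["contribution"] / totals, np.nan)
    by_med["undefined"] = totals <= 0
    by_med["group"] = by_med["mediator"].map(groups)
    gb = by_med.groupby(["region_id", "tcm", "group"])["contribution"]
    by_group = gb.agg(group_sum="sum", group_max="max").reset_index()

    dom_rows = []
    for (rid, tcm), sub in by_med.groupby(["region_id", "tcm"]):
        total = sub["contribution"].sum()
        if total <= 0:
            dom_rows.append((rid, tcm, None, None, None, False))
            continue
        dom_med = sub.loc[sub["contribution"].idxmax(), "mediator"]
        g = by_group[(by_group["region_id"] == rid) & (by_group["tcm"] == tcm)]
        gs = g.set_index("group")["group_sum"]
        gm = g.set_index("group")["group_max"]
        tie = bool(np.isclose(gs.max(), gs.min())) and len(gs) > 1
        dom_rows.append((rid, tcm, dom_med, gs.idxmax(), gm.idxmax(), tie))
    dominance = pd.DataFrame(dom_rows, columns=[
        "region_id", "tcm", "dominant_mediator",
        "dominant_group_sum", "dominant_group_max", "group_tie",
    ])
    return ContributionTable(by_mediator=by_med, by_group=by_group, dominance=dominance)


def per_cell_dominance(fits: pd.DataFrame) -> pd.DataFrame:
    """Dominant mediator group per cell under the sum rule and the max rule.

    ``fits`` needs columns cell, mediator, contribution.  Cells whose
    contributions are all zero are left unclassified (None).  The returned
    frame also lets callers compute the two rules' agreement rate.
    """
    rows = []
    for cell, sub in fits.groupby("cell"):
        total = sub["contribution"].sum()
        if total <= 0:
            rows.append((cell, None, None, False))
            continue
        sub = sub.assign(group=sub["mediator"].map(mediator_group))
        g = sub.groupby("group")["contribution"]
        dom_sum = g.sum().idxmax()
        dom_max = g.max().idxmax()
        rows.append((cell, dom_sum, dom_max, dom_sum == dom_max))
    return pd.DataFrame(rows, columns=["cell", "dominant_group_sum",
                                       "dominant_group_max", "rules_agree"])
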