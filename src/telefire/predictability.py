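"""Per-cell burned-area predictability from lagged teleconnection indices.

For each cell and index the 0..24-month lagged copies form the predictor
matrix of a PLS regression on fire-season BA anomalies.  The number of
components is chosen by 10-fold cross-validation on a 70% training split
(k minimizing mean squared prediction error, k_max = 10); predictability is
the coefficient of determination R² between predicted and observed BA on
the held-out 30%.  A cell counts as predictable when the model F-test is
significant at the 0.05 level; by default that F-test is evaluated on the
held-out split (regressing observed on predicted), which keeps the type-I
rate at its nominal level — PLS components are response-supervised, so the
classical training-data F-test is strongly anticonservative.  The
training-data variant (numerator df = k) remains available via
``p_value_mode="train"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pls import coef_path, fit_plsr
from .preprocess import CellSampleSet

__all__ = [
    "PredictabilityResult",
    "PredictabilityMap",
    "assess_predictability",
    "fit_multi_tcm",
    "affected_area_fraction",
]


@dataclass
class PredictabilityResult:
    r2_test: float
    p_f: float
    significant: bool
    k_selected: int
    cv_mse: np.ndarray  # mean CV MSE per candidate k (1..k_max)
    n_train: int
    n_test: int


def _stratified_split(years: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Per-year split: each year contributes ~(1-train_frac) of its samples
    to the test set, avoiding whole-season leakage imbalance."""
    test_idx = []
    for y in np.unique(years):
        idx = np.flatnonzero(years == y)
        rng.shuffle(idx)
        n_test = int(round((1.0 - train_frac) * idx.size))
        test_idx.extend(idx[:n_test])
    test = np.zeros(years.size, dtype=bool)
    test[test_idx] = True
    return ~test, test


def _kfold_indices(n: int, folds: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return np.array_split(order, folds)


def _cv_select_k(X, y, *, k_max, folds, rng):
    """Mean CV MSE per k (one nested-path fit per fold); argmin -> k."""
    n = X.shape[0]
    folds = min(folds, n)
    mse = np.zeros(k_max)
    counts = 0
    for test in _kfold_indices(n, folds, rng):
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        if train.size < 3 or np.std(y[train]) <= 0:
            continue
        icpt, coefs = coef_path(X[train], y[train], k_max)
        pred = X[test] @ coefs.T + icpt  # (n_test, k_max)
        mse += np.sum((pred - y[test][:, None]) ** 2, axis=0)
        counts += test.size
    if counts == 0:
        return 1, np.full(k_max, np.nan)
    mse /= counts
    return int(np.argmin(mse)) + 1, mse


def _r2_score(obs: np.ndarray, pred: np.ndarray) -> float:
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst <= 0:
        return 0.0
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def _test_split_pvalue(obs: np.ndarray, pred: np.ndarray) -> float:
    """F-test of the observed-vs-predicted regression on the held-out split."""
    if obs.size < 3 or np.std(pred) <= 0 or np.std(obs) <= 0:
        return 1.0
    return float(stats.pearsonr(obs, pred).pvalue)


def _train_f_pvalue(r2: float, k: int, n: int) -> float:
    if k <= 0 or n - k - 1 <= 0 or not (0 <= r2 < 1):
        return 1.0
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return float(stats.f.sf(f, k, n - k - 1))


def assess_predictability(
    samples: CellSampleSet | np.ndarray,
    response: np.ndarray | None = None,
    *,
    years: np.ndarray | None = None,
    train_frac: float = 0.7,
    cv_folds: int = 10,
    k_max: int = 10,
    alpha: float = 0.05,
    p_value_mode: str = "test",
    seed: int | np.random.Generator = 0,
) -> PredictabilityResult:
    """Train/test PLSR predictability of one cell's response from one design.

    Accepts either a ``CellSampleSet`` or an explicit (X, y) pair (the 3-TCM
    combined model passes a 75-column design).
    """
    if isinstance(samples, CellSampleSet):
        X, y, yrs = samples.design, samples.response, samples.years
    else:
        X = np.asarray(samples, dtype=float)
        y = np.asarray(response, dtype=float)
        yrs = years if years is not None else np.arange(y.size)
    if p_value_mode not in ("test", "train"):
        raise ValueError("p_value_mode must be 'test' or 'train'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    train, test = _stratified_split(np.asarray(yrs), train_frac, rng)
    k_max_eff = int(min(k_max, X.shape[1], train.sum() - 2))
    k, cv_mse = _cv_select_k(X[train], y[train], k_max=k_max_eff,
                             folds=cv_folds, rng=rng)
    model = fit_plsr(X[train], y[train], k)
    pred = model.predict(X[test])
    r2_test = _r2_score(y[test], pred)
    if p_value_mode == "test":
        p_f = _test_split_pvalue(y[test], pred)
    else:
        p_f = _train_f_pvalue(model.r2_train(), model.k, int(train.sum()))
    return PredictabilityResult(
        r2_test=r2_test, p_f=p_f, significant=bool(p_f < alpha),
        k_selected=model.k, cv_mse=cv_mse,
        n_train=int(train.sum()), n_test=int(test.sum()),
    )


def fit_multi_tcm(
    sample_sets: list[CellSampleSet],
    **kwargs,
) -> PredictabilityResult:
    """Combined model over several indices: concatenated lagged designs.

    All sample sets must share the response (same cell / fire season); the
    designs are stacked column-wise (3 TCMs x 25 lags = 75 predictors) and
    assessed under the identical CV / split / significance protocol.
    """
    if not sample_sets:
        raise ValueError("need at least one sample set")
    y = sample_sets[0].response
    for s in sample_sets[1:]:
        if s.n_samples != y.size:
            raise ValueError("sample sets are not on a common frame")
    X = np.hstack([s.design for s in sample_sets])
    return assess_predictability(X, y, years=sample_sets[0].years, **kwargs)


@dataclass
class PredictabilityMap:
    """Per-cell, per-TCM predictability with the cross-TCM maximum.

    ``r2`` and ``p`` are (n_tcm, nlat, nlon); ``significant`` likewise.
    ``max_map`` holds, per cell, the highest test R² among significant fits
    (NaN where no index is significant).
    """

    tcm_names: list
    r2: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    mask: np.ndarray

    @property
    def max_map(self) -> np.ndarray:
        r2 = np.where(self.significant, self.r2, -np.inf)
        best = r2.max(axis=0) if len(self.tcm_names) else np.full(self.mask.shape, -np.inf)
        return np.where(np.isfinite(best), best, np.nan)

    def hotspot_field(self) -> np.ndarray:
        """Max-predictability field for the Gi* stage: the highest test R²
        over all indices at each burnable cell, *without* the significance
        gate.  Significance defines "predictable" for the area fractions;
        the clustered field itself stays continuous — gating it to a
        spike-at-zero mixture would break the Gi* normal approximation and
        manufacture hot spots out of chance-adjacent significant cells."""
        f = self.r2.max(axis=0) if len(self.tcm_names) else np.zeros(self.mask.shape)
        return np.where(self.mask, f, np.nan)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, name in enumerate(self.tcm_names):
            for (i, j) in np.argwhere(self.mask):
                rows.append((name, i, j, self.r2[t, i, j], self.p[t, i, j],
                             bool(self.significant[t, i, j])))
        return pd.DataFrame(rows, columns=["tcm", "row", "col", "r2_test", "p_f", "significant"])


def affected_area_fraction(
    pmap: PredictabilityMap,
    region_cells=None,
) -> dict:
    """Fraction of burnable cells where BA is significantly predictable.

    Returns one fraction per index plus "Any" (at least one index
    significant).  With ``region_cells`` the denominator restricts to
    burnable cells of that region.
    """
    mask = pmap.mask.copy()
    if region_cells is not None:
        sel = np.zeros_like(mask)
        for (i, j) in region_cells:
            sel[i, j] = True
        mask &= sel
    denom = int(mask.sum())
    if denom == 0:
        raise ValueError("empty burnable mask / region")
    out = {}
    for t, name in enumerate(pmap.tcm_names):
        out[name] = float((pmap.significant[t] & mask).sum() / denom)
    out["Any"] = float((pmap.significant.any(axis=0) & mask).sum() / denom)
    return out
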