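"""Partial least squares regression (PLS1) for lagged-predictor designs.

The predictability stage regresses fire-season burned-area anomalies on the
0..24-month lagged copies of one (or three) teleconnection index, projecting
the lagged design onto a small number of covariance-maximizing components

    X_j = sum_t  TCM_t * w_tj            (component scores)
    BA  = sum_j  c_j * X_j + eps         (component regression)

with w and c estimated jointly by NIPALS.  Only a univariate response is
needed here, so the classic PLS1 recursion applies; its components are
*nested* (the k-component model is the first k components of the
k_max-component model), which lets a single fit serve every candidate k
during cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSRModel", "fit_plsr"]

_EPS = np.finfo(float).eps


@dataclass
class PLSRModel:
    """Fitted PLS1 model on a centered/scaled lagged design.

    Attributes
    ----------
    weights : (p, k) array
        Column weights w_tj mapping (standardized) predictors to scores.
    x_loadings : (p, k) array
        Deflation loadings p_j.
    c : (k,) array
        Component regression coefficients c_j.
    coef : (p,) array
        Collapsed coefficients on the standardized predictor scale,
        B = W (P'W)^-1 c.
    scores : (n, k) array
        Training component scores; mutually orthogonal.
    k : int
        Number of components actually extracted (may be < requested when
        the residual predictor matrix becomes numerically empty).
    """

    weights: np.ndarray
    x_loadings: np.ndarray
    c: np.ndarray
    coef: np.ndarray
    scores: np.ndarray
    k: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    fitted_values: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.x_mean) / self.x_scale
        return self.y_mean + Z @ self.coef

    def r2_train(self) -> float:
        y = self.fitted_values + self.residuals
        sst = np.sum((y - y.mean()) ** 2)
        if sst <= 0:
            return 0.0
        return 1.0 - np.sum(self.residuals**2) / sst


def _standardize(X: np.ndarray, scale: bool):
    x_mean = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
    else:
        x_scale = np.ones(X.shape[1])
    return (X - x_mean) / x_scale, x_mean, x_scale


def _nipals_path(Z: np.ndarray, yc: np.ndarray, k_max: int):
    """Run the PLS1 recursion, returning per-component W, P, c.

    Stops early when the covariance between the deflated predictors and the
    response response is numerically zero (degenerate / collinear designs
    deflate cleanly instead of failing).
    """
    n, p = Z.shape
    Zd = Z.copy()
    yd = yc.copy()
    W, P, C, T = [], [], [], []
    ref = np.linalg.norm(Z.T @ yc) + _EPS
    for _ in range(k_max):
        w = Zd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * ref:
            break
        w /= nw
        t = Zd @ w
        tt = t @ t
        if tt <= _EPS * n:
            break
        pj = Zd.T @ t / tt
        cj = (yd @ t) / tt
        Zd -= np.outer(t, pj)
        yd = yd - cj * t
        W.append(w)
        P.append(pj)
        C.append(cj)
        T.append(t)
    if not W:
        return (np.zeros((p, 0)), np.zeros((p, 0)), np.zeros(0), np.zeros((n, 0)))
    return (np.column_stack(W), np.column_stack(P), np.asarray(C), np.column_stack(T))


def _coef_from_components(W, P, c, k):
    # B_k = W_k (P_k' W_k)^-1 c_k ; P'W is unit upper triangular for PLS1
    Wk, Pk, ck = W[:, :k], P[:, :k], c[:k]
    R = Pk.T @ Wk
    return Wk @ np.linalg.solve(R, ck)


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    *,
    scale: bool = True,
) -> PLSRModel:
    """Fit a k-component PLS1 regression of ``y`` on the columns of ``X``.

    Predictors are column-centered and (by default) scaled to unit variance;
    the response is centered.  Raises ``ValueError`` for a zero-variance
    response, which cannot define components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have incompatible lengths")
    if n <= k:
        raise ValueError(f"need n_samples > k (got n={n}, k={k})")
    if np.std(y) <= 0:
        raise ValueError("degenerate response: zero variance")
    Z, x_mean, x_scale = _standardize(X, scale)
    y_mean = y.mean()
    W, P, c, T = _nipals_path(Z, y - y_mean, min(k, p, n - 1))
    k_eff = W.shape[1]
    if k_eff:
        coef = _coef_from_components(W, P, c, k_eff)
    else:
        coef = np.zeros(p)
    fitted = y_mean + Z @ coef
    return PLSRModel(
        weights=W,
        x_loadings=P,
        c=c,
        coef=coef,
        scores=T,
        k=k_eff,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        fitted_values=fitted,
        residuals=y - fitted,
    )


def coef_path(X: np.ndarray, y: np.ndarray, k_max: int, *, scale: bool = True):
    """Coefficients (intercept, B) for every k in 1..k_max from one fit.

    Exploits component nesting: the k-component coefficients only need the
    first k columns of W/P/c.  Returns ``(intercepts, coefs)`` with
    ``coefs[k-1]`` the standardized-scale coefficient vector for k
    components, mapped back to the raw predictor scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Z, x_mean, x_scale = _standardize(X, scale)
    y_mean = y.mean()
    W, P, c, _ = _nipals_path(Z, y - y_mean, min(k_max, p, n - 1))
    k_eff = W.shape[1]
    coefs = np.zeros((k_max, p))
    intercepts = np.full(k_max, y_mean)
    for kk in range(1, k_max + 1):
        if kk <= k_eff:
            b = _coef_from_components(W, P, c, kk)
        elif k_eff:
            b = _coef_from_components(W, P, c, k_eff)
        else:
            b = np.zeros(p)
        braw = b / x_scale
        coefs[kk - 1] = braw
        intercepts[kk - 1] = y_mean - x_mean @ braw
    return intercepts, coefs
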