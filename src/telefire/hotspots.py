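"""Getis-Ord Gi* hot/cold-spot analysis on a regular lat/lon grid.

For each cell the Gi* statistic compares the sum of the predictability field
over the cell's neighborhood (queen contiguity *including the cell itself*)
with what a random draw from the global field would give:

    Gi* = (sum_j w_ij x_j - xbar * W_i) /
          (S * sqrt((n * sum_j w_ij^2 - W_i^2) / (n - 1)))

with xbar and S the global (population) mean and standard deviation over all
finite burnable cells, n their count and W_i = sum_j w_ij.  Weights are
binary here, so sum w² = W.  z-scores are classified two-sided into
hot/cold tiers at the 0.10 / 0.05 / 0.01 levels.  Neighborhoods wrap across
the ±180° meridian (the longitude axis) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = ["HotspotMap", "Region", "gistar", "extract_hotspots", "classify"]

TIERS = (0.10, 0.05, 0.01)
# class codes: negative = cold, positive = hot, magnitude = tier
COLD99, COLD95, COLD90, NOT_SIG, HOT90, HOT95, HOT99 = -3, -2, -1, 0, 1, 2, 3
CLASS_NAMES = {
    COLD99: "cold-99", COLD95: "cold-95", COLD90: "cold-90",
    NOT_SIG: "not-significant",
    HOT90: "hot-90", HOT95: "hot-95", HOT99: "hot-99",
}


@dataclass
class HotspotMap:
    z: np.ndarray
    p: np.ndarray
    cls: np.ndarray  # integer class codes, see CLASS_NAMES
    valid: np.ndarray = field(repr=False, default=None)

    def class_name(self, cell) -> str:
        return CLASS_NAMES[int(self.cls[cell])]


@dataclass(frozen=True)
class Region:
    region_id: int
    cells: tuple
    area_fraction: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _neighbor_sum(a: np.ndarray, wrap_lon: bool) -> np.ndarray:
    """3x3 box sum (self included); longitude wraps, latitude does not."""
    if wrap_lon:
        ap = np.concatenate([a[:, -1:], a, a[:, :1]], axis=1)
        s = ndimage.uniform_filter(ap, size=3, mode="constant", cval=0.0) * 9.0
        return s[:, 1:-1]
    return ndimage.uniform_filter(a, size=3, mode="constant", cval=0.0) * 9.0


def gistar(values: np.ndarray, mask: np.ndarray | None = None, *,
           wrap_lon: bool = True, permutations: int = 0,
           rng: np.random.Generator | None = None) -> HotspotMap:
    """Gi* z-score, p-value and hot/cold class per cell.

    Parameters
    ----------
    values : 2-D field; NaN cells are excluded (and excluded from x̄, S, n).
    mask : optional boolean burnable mask; non-burnable cells are excluded.
    permutations : if > 0, p-values come from that many random relabelings
        of the field over the valid cells instead of the normal
        approximation.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D grid")
    valid = np.isfinite(x)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    xv = x[valid]
    xbar = xv.mean()
    S = xv.std(ddof=0)  # population sd, as in the classic Gi* formulation
    if S <= 0:
        raise ValueError("zero variance: constant field has no hot spots")

    def _zfield(f2d):
        f0 = np.where(valid, f2d, 0.0)
        sum_wx = _neighbor_sum(f0, wrap_lon)
        sum_w = _neighbor_sum(valid.astype(float), wrap_lon)
        var_term = (n * sum_w - sum_w**2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (sum_wx - xbar * sum_w) / (S * np.sqrt(var_term))
        z[~valid] = np.nan
        z[valid & (var_term <= 0)] = 0.0  # neighborhood covers the whole field
        return z

    sum_w_self = _neighbor_sum(valid.astype(float), wrap_lon)
    if np.any(sum_w_self[valid] <= 1):
        warnings.warn("isolated cell(s): neighborhood reduces to self only", stacklevel=2)
    z = _zfield(x)
    if permutations > 0:
        rng = rng or np.random.default_rng()
        exceed = np.zeros_like(z)
        zobs = np.abs(z)
        xs = x[valid].copy()
        f = x.copy()
        for _ in range(permutations):
            rng.shuffle(xs)
            f[valid] = xs
            zp = _zfield(f)
            exceed += (np.abs(zp) >= zobs).astype(float)
        p = (exceed + 1.0) / (permutations + 1.0)
        p[~valid] = np.nan
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    cls = classify(z, p)
    return HotspotMap(z=z, p=p, cls=cls, valid=valid)


def classify(z: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Map (z, p) to the seven hot/cold significance classes."""
    cls = np.zeros(z.shape, dtype=int)
    sign = np.sign(np.nan_to_num(z)).astype(int)
    for code, alpha in ((1, 0.10), (2, 0.05), (3, 0.01)):
        sel = np.isfinite(p) & (p < alpha)
        cls[sel] = code * sign[sel]
    cls[~np.isfinite(z)] = NOT_SIG
    return cls


def _label_with_wrap(binary: np.ndarray, wrap_lon: bool) -> np.ndarray:
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # rook adjacency
    labels, _ = ndimage.label(binary, structure=structure)
    if wrap_lon and binary.shape[1] > 1:
        # merge labels adjacent across the longitude seam
        for r in range(binary.shape[0]):
            a, b = labels[r, 0], labels[r, -1]
            if a and b and a != b:
                labels[labels == max(a, b)] = min(a, b)
    return labels


def extract_hotspots(hmap: HotspotMap, *, min_cells: int = 5,
                     burnable: np.ndarray | None = None,
                     wrap_lon: bool = True) -> list[Region]:
    """Connected components (rook adjacency) of hot-99 cells.

    Components smaller than ``min_cells`` are discarded; area fractions are
    relative to the burnable-cell count.
    """
    hot = hmap.cls == HOT99
    labels = _label_with_wrap(hot, wrap_lon)
    if burnable is None:
        burnable = hmap.valid if hmap.valid is not None else np.ones(hot.shape, bool)
    denom = max(int(np.asarray(burnable, bool).sum()), 1)
    regions = []
    rid = 0
    for lab in np.unique(labels):
        if lab == 0:
            continue
        cells = tuple(map(tuple, np.argwhere(labels == lab)))
        if len(cells) < min_cells:
            continue
        rid += 1
        regions.append(Region(region_id=rid, cells=cells,
                              area_fraction=len(cells) / denom))
    regions.sort(key=lambda r: -r.n_cells)
    return [Region(i + 1, r.cells, r.area_fraction) for i, r in enumerate(regions)]
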