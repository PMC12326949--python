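"""Synthetic coupled world: teleconnection indices, mediators and burned area.

Generates monthly grids with a *known* causal structure so every pipeline
stage has recoverable ground truth:

* each teleconnection-mode index (TCM) is a stationary mean-zero AR(1)
  process with unit marginal variance;
* inside a planted region, a mediator responds to one TCM at lag ``i``
  (slope = sign * strength) on top of a sinusoidal seasonal cycle, linear
  trend and Gaussian noise; elsewhere it is pure seasonal+trend+noise;
* burned-area anomalies in the region respond linearly to the mediator's
  anomalous part (signal + mediator noise, standardized) at lag ``j`` —
  a genuine mediation chain in which both links are noisy;
* the BA climatology is scaled so three consecutive months dominate, making
  the fire-season detector's target part of the ground truth.

With unit TCM variance, ``strength = s`` and ``noise_sd = 1`` each link of
the chain has true R² = s²/(s²+1) (0.5 at s = 1).

Reproducibility: one root ``SeedSequence`` per world, split per variable by
fixed spawn keys — TCM k draws from ``(0, k)``, mediator m from ``(1, m)``
(m indexed in the canonical mediator order), BA from ``(2, 0)`` — so adding
a mediator never perturbs the TCM or BA draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import IndexSeries, MonthlyGrid

__all__ = [
    "WEATHER_MEDIATORS",
    "FUEL_MEDIATORS",
    "MEDIATOR_NAMES",
    "TCM_NAMES",
    "PlantedPathway",
    "WorldConfig",
    "World",
    "generate_world",
]

WEATHER_MEDIATORS = ("Tmax", "ET0", "VPD", "Wind")
FUEL_MEDIATORS = ("NDVI", "EVI", "FPAR", "SM")
MEDIATOR_NAMES = WEATHER_MEDIATORS + FUEL_MEDIATORS
TCM_NAMES = ("AO", "POL", "NAO", "EAWR", "TNA", "TSA", "IOD", "ENSO", "PNA", "WP", "AAO")

MAX_LAG = 24
_SPINUP = MAX_LAG  # extra leading months so lagged influences exist from t=0


@dataclass(frozen=True)
class PlantedPathway:
    """A TCM -> mediator -> BA chain planted in a rectangular cell region."""

    tcm_index: int
    mediator_name: str
    region: tuple  # ((row0, row1), (col0, col1)) half-open slices
    lag_tcm_to_mediator: int  # i, months
    lag_mediator_to_ba: int  # j, months
    sign: int = 1
    strength: float = 1.0

    def cells(self):
        (r0, r1), (c0, c1) = self.region
        return [(r, c) for r in range(r0, r1) for c in range(c0, c1)]


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world.

    Defaults mirror a 22-year (2003-2024-style) monthly record, all 11
    teleconnection modes and all 8 mediators on a 20x20 burnable grid.
    """

    n_years: int = 22
    grid_shape: tuple = (20, 20)
    n_tcms: int = 11
    ar_coeff: float | list = 0.5
    pathway_specs: list = field(default_factory=list)
    noise_sd: float = 1.0
    trend_slope: float = 0.002  # units/month, removed again by detrending
    seasonal_amplitude: float = 0.5
    fire_peak_start_month: int = 7  # Jul-Aug-Sep climatological fire season
    fire_peak_level: float = 5.0
    fire_base_level: float = 0.1
    ba_link: str = "identity"  # or "exp" for a nonnegative burned fraction
    mediator_names: tuple = MEDIATOR_NAMES
    start_year: int = 2003
    seed: int = 0
    burnable_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.n_years < 5:
            raise ValueError("n_years must be >= 5 to leave usable fire seasons after lagging")
        ar = np.atleast_1d(np.asarray(self.ar_coeff, dtype=float))
        if np.any(np.abs(ar) >= 1):
            raise ValueError("ar_coeff must lie strictly inside (-1, 1)")
        if self.ba_link not in ("identity", "exp"):
            raise ValueError("ba_link must be 'identity' or 'exp'")
        mask = self.burnable_mask
        if mask is None:
            mask = np.ones(self.grid_shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(self.grid_shape):
            raise ValueError("burnable_mask shape does not match grid_shape")
        self.burnable_mask = mask
        for pw in self.pathway_specs:
            i, j = pw.lag_tcm_to_mediator, pw.lag_mediator_to_ba
            if not (0 <= i <= MAX_LAG and 0 <= j <= MAX_LAG and i + j <= MAX_LAG):
                raise ValueError(f"planted lags ({i}, {j}) outside [0, {MAX_LAG}] with i+j <= {MAX_LAG}")
            if not (0 <= pw.tcm_index < self.n_tcms):
                raise ValueError("pathway tcm_index out of range")
            if pw.mediator_name not in self.mediator_names:
                raise ValueError(f"unknown mediator {pw.mediator_name!r}")
            (r0, r1), (c0, c1) = pw.region
            nlat, nlon = self.grid_shape
            if not (0 <= r0 < r1 <= nlat and 0 <= c0 < c1 <= nlon):
                raise ValueError("pathway region outside the grid")
            if not mask[r0:r1, c0:c1].all():
                raise ValueError("pathway region includes non-burnable cells")
        if 12 * self.n_years <= MAX_LAG + 12:
            raise ValueError("record too short to form any lagged sample")

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    @property
    def time(self) -> pd.PeriodIndex:
        return pd.period_range(start=f"{self.start_year}-01", periods=self.n_months, freq="M")

    @property
    def ar_coeffs(self) -> np.ndarray:
        ar = np.atleast_1d(np.asarray(self.ar_coeff, dtype=float))
        if ar.size == 1:
            ar = np.repeat(ar, self.n_tcms)
        if ar.size != self.n_tcms:
            raise ValueError("ar_coeff must be scalar or length n_tcms")
        return ar


@dataclass
class World:
    """A generated world: inputs for the pipeline plus its ground truth."""

    config: WorldConfig
    indices: list  # list[IndexSeries]
    mediators: dict  # name -> MonthlyGrid
    ba: MonthlyGrid
    ground_truth: list  # list[PlantedPathway]

    @property
    def mask(self) -> np.ndarray:
        return self.config.burnable_mask


def _rng(seed: int, key: tuple) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _ar1(rng: np.random.Generator, phi: float, n: int) -> np.ndarray:
    """Stationary unit-variance AR(1): x_t = phi x_{t-1} + sqrt(1-phi²) e_t."""
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    e = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t - 1]
    return x


def _seasonal(n_ext: int, amplitude: float, phase: float) -> np.ndarray:
    t = np.arange(-_SPINUP, n_ext - _SPINUP, dtype=float)
    return amplitude * np.sin(2 * np.pi * t / 12.0 + phase)


def generate_world(config: WorldConfig) -> World:
    """Generate one world (deterministic for a fixed config seed)."""
    cfg = config
    nlat, nlon = cfg.grid_shape
    n = cfg.n_months
    n_ext = n + _SPINUP
    time = cfg.time
    mask = cfg.burnable_mask
    seed = cfg.seed

    # --- TCM indices (extended axis; the public series drops the spin-up) ---
    tcm_ext = np.empty((cfg.n_tcms, n_ext))
    for k, phi in enumerate(cfg.ar_coeffs):
        tcm_ext[k] = _ar1(_rng(seed, (0, k)), phi, n_ext)
    names = list(TCM_NAMES[: cfg.n_tcms])
    names += [f"TCM{k}" for k in range(len(names), cfg.n_tcms)]
    indices = [IndexSeries(tcm_ext[k, _SPINUP:], time, names[k]) for k in range(cfg.n_tcms)]

    pathways_by_mediator: dict[str, list[PlantedPathway]] = {}
    for pw in cfg.pathway_specs:
        pathways_by_mediator.setdefault(pw.mediator_name, []).append(pw)

    # --- Mediators ---
    mediators: dict[str, MonthlyGrid] = {}
    med_anom_ext: dict[str, np.ndarray] = {}  # anomalous part (signal + noise)
    canonical = {name: m for m, name in enumerate(MEDIATOR_NAMES)}
    for m, name in enumerate(cfg.mediator_names):
        rng = _rng(seed, (1, canonical.get(name, 100 + m)))
        phase = rng.uniform(0, 2 * np.pi)
        anom = rng.standard_normal((n_ext, nlat, nlon)) * cfg.noise_sd
        for pw in pathways_by_mediator.get(name, []):
            i = pw.lag_tcm_to_mediator
            drive = pw.sign * pw.strength * np.roll(tcm_ext[pw.tcm_index], i)
            drive[:i] = 0.0  # roll wraps; zero the undefined head
            (r0, r1), (c0, c1) = pw.region
            anom[:, r0:r1, c0:c1] += drive[:, None, None]
        med_anom_ext[name] = anom
        base = _seasonal(n_ext, cfg.seasonal_amplitude, phase)[:, None, None]
        base = base + cfg.trend_slope * np.arange(-_SPINUP, n, dtype=float)[:, None, None]
        full = (base + anom)[_SPINUP:]
        full[:, ~mask] = np.nan
        role = "weather-mediator" if name in WEATHER_MEDIATORS else "fuel-mediator"
        mediators[name] = MonthlyGrid(full, time, mask, name=name, units="anom", variable_role=role)

    # --- Burned area ---
    rng = _rng(seed, (2, 0))
    ba_anom = rng.standard_normal((n_ext, nlat, nlon)) * cfg.noise_sd
    for pw in cfg.pathway_specs:
        j = pw.lag_mediator_to_ba
        anom = med_anom_ext[pw.mediator_name]
        med_sd = np.sqrt(pw.strength**2 + cfg.noise_sd**2)
        shifted = np.roll(anom, j, axis=0)
        shifted[:j] = 0.0
        (r0, r1), (c0, c1) = pw.region
        ba_anom[:, r0:r1, c0:c1] += pw.strength * shifted[:, r0:r1, c0:c1] / med_sd
    month_of = np.asarray(cfg.time.month)
    clim = np.full(12, cfg.fire_base_level)
    for k in range(3):
        clim[(cfg.fire_peak_start_month - 1 + k) % 12] = cfg.fire_peak_level
    ba = ba_anom[_SPINUP:] + clim[month_of - 1][:, None, None]
    if cfg.ba_link == "exp":
        ba = np.exp(0.1 * ba)
    ba[:, ~mask] = np.nan
    ba_grid = MonthlyGrid(ba, time, mask, name="BA", units="anomaly-scale burned fraction",
                          variable_role="BA")
    return World(cfg, indices, mediators, ba_grid, list(cfg.pathway_specs))
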