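"""End-to-end attribution model: data in, fitted results out.

``TeleconnectionFireModel`` bundles the burned-area cube, mediator cubes,
index series and burnable mask; ``fit()`` runs the stage chain

    preprocess -> per-index PLSR predictability -> max map -> Gi* hot spots
    -> per-hot-spot lag profiles -> mediation pathways -> aggregation

and returns a ``TeleconnectionFireResults`` carrying per-stage tables, the
dominance calls and a ``summary()``.  All stochastic steps (train/test
split, CV folds) derive per-cell seeds from the single run seed, so a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hotspots as hs
from . import io as tio
from .lags import build_lag_profile, gated_correlations
from .mediation import aggregate_contributions, pathway_contribution_frame, per_cell_dominance
from .predictability import (PredictabilityMap, affected_area_fraction,
                             assess_predictability, fit_multi_tcm)
from .preprocess import build_samples, detect_fire_season, preprocess_series
from .synthetic import World

logger = logging.getLogger("telefire")

ALL_STAGES = ("predictability", "hotspots", "lags", "pathways")


@dataclass
class PipelineConfig:
    """Run settings; the defaults are the study constants (lags 0-24,
    alpha 0.05, 70/30 split, 10 folds, 3-month fire season)."""

    response_kind: str = "BA"  # or "FRP" (95th-percentile aggregate cube)
    max_lag: int = 24
    alpha: float = 0.05
    train_frac: float = 0.7
    cv_folds: int = 10
    k_max: int = 10
    min_samples: int = 10
    min_cells: int = 5
    p_value_mode: str = "test"  # or "train" (anticonservative; see docs)
    lag_denominator: str = "all"  # or "significant"
    season_aggregate: bool = False
    wrap_lon: bool = True
    n_top_tcms: int = 3
    pathways_scope: str = "hotspots"  # or "global"
    stages: tuple = ALL_STAGES
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _cell_rng(seed: int, key: tuple) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,) + key))


class TeleconnectionFireModel:
    """Attribution of burned-area variability to lagged climate modes.

    Parameters
    ----------
    ba : MonthlyGrid
        Monthly burned-area (or 95th-percentile FRP) cube.
    mediators : dict name -> MonthlyGrid
        Weather and fuel mediator cubes on the same axis.
    indices : list of IndexSeries
        Teleconnection-mode indices on the same monthly axis.
    mask : optional boolean burnable grid (defaults to the BA mask).
    config : PipelineConfig
    """

    def __init__(self, ba, mediators, indices, mask=None, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.ba = ba
        self.mediators = dict(mediators)
        self.indices = list(indices)
        self.mask = np.asarray(mask if mask is not None else ba.mask, dtype=bool)
        n = ba.n_months
        for name, g in self.mediators.items():
            if g.n_months != n or not g.time.equals(ba.time):
                raise ValueError(f"mediator {name!r}: time axis misaligned with BA")
        for s in self.indices:
            if not s.time.equals(ba.time):
                raise ValueError(f"index {s.name!r}: time axis misaligned with BA")
        if self.config.max_lag > n - 36:
            raise ValueError("max_lag too large for the record length")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_world(cls, world: World, config: PipelineConfig | None = None):
        return cls(world.ba, world.mediators, world.indices, world.mask, config)

    @classmethod
    def from_files(cls, cube_path, indices_path, config: PipelineConfig | None = None):
        grids = tio.read_cube(cube_path)
        cfg = config or PipelineConfig()
        ba = grids.pop(cfg.response_kind if cfg.response_kind in grids else "BA")
        indices = tio.read_indices(indices_path)
        return cls(ba, grids, indices, ba.mask, cfg)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int | None = None) -> "TeleconnectionFireResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        time = self.ba.time
        nlat, nlon = self.mask.shape
        warnings_log: list[str] = []

        # preprocess: seasons + anomaly series per burnable cell
        seasons = {}
        ba_anom = {}
        cells = [tuple(c) for c in np.argwhere(self.mask)]
        for cell in cells:
            raw = self.ba.cell_series(cell)
            season = detect_fire_season(raw, time)
            if season is None:
                warnings_log.append(f"cell {cell}: no fire season (all-zero BA)")
                continue
            seasons[cell] = season
            ba_anom[cell] = preprocess_series(raw, time, anomaly=True)
        tcm_detr = {s.name: preprocess_series(s.values, time, anomaly=False)
                    for s in self.indices}
        tcm_names = [s.name for s in self.indices]
        logger.info("preprocess: %d/%d cells with a fire season", len(seasons), len(cells))

        def tcm_samples(cell, name):
            return build_samples(ba_anom[cell], tcm_detr[name], time, seasons[cell],
                                 max_lag=cfg.max_lag, min_samples=cfg.min_samples,
                                 season_aggregate=cfg.season_aggregate)

        res = TeleconnectionFireResults(model=self, config=cfg, seed=seed,
                                        seasons=seasons, warnings=warnings_log)
        if "predictability" not in cfg.stages:
            return res

        # stage: per-index predictability
        nt = len(tcm_names)
        r2 = np.full((nt, nlat, nlon), np.nan)
        pf = np.full((nt, nlat, nlon), np.nan)
        sig = np.zeros((nt, nlat, nlon), dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for cell, season in seasons.items():
                for t, name in enumerate(tcm_names):
                    ss = tcm_samples(cell, name)
                    if ss.insufficient:
                        continue
                    r = assess_predictability(
                        ss, train_frac=cfg.train_frac, cv_folds=cfg.cv_folds,
                        k_max=cfg.k_max, alpha=cfg.alpha, p_value_mode=cfg.p_value_mode,
                        seed=_cell_rng(seed, (t,) + cell))
                    r2[t][cell], pf[t][cell], sig[t][cell] = r.r2_test, r.p_f, r.significant
        res.predictability = PredictabilityMap(tcm_names, r2, pf, sig, self.mask)
        res.affected_fraction = affected_area_fraction(res.predictability)
        logger.info("predictability: affected fractions %s", res.affected_fraction)
        if "hotspots" not in cfg.stages:
            return res

        # stage: Gi* hot spots on the max-predictability field
        field_ = res.predictability.hotspot_field()
        try:
            res.hotspot_map = hs.gistar(field_, self.mask, wrap_lon=cfg.wrap_lon)
        except ValueError as exc:  # constant field (e.g. nothing significant)
            warnings_log.append(f"hotspots: {exc}")
            res.regions = []
            return res
        res.regions = hs.extract_hotspots(res.hotspot_map, min_cells=cfg.min_cells,
                                          burnable=self.mask, wrap_lon=cfg.wrap_lon)
        logger.info("hotspots: %d region(s)", len(res.regions))

        # per-region dominant indices (ranked by predictable-area fraction,
        # then mean significant R²) and the combined top-3 model
        region_rank = {}
        multi_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for reg in res.regions:
                frac = affected_area_fraction(res.predictability, reg.cells)
                mean_r2 = {}
                for t, name in enumerate(tcm_names):
                    vals = [r2[t][c] for c in reg.cells if sig[t][c]]
                    mean_r2[name] = float(np.mean(vals)) if vals else 0.0
                order = sorted(tcm_names, key=lambda m: (-frac[m], -mean_r2[m], m))
                top = order[: cfg.n_top_tcms]
                region_rank[reg.region_id] = top
                for cell in reg.cells:
                    if cell not in seasons:
                        continue
                    sets = [tcm_samples(cell, m) for m in top]
                    if any(s.insufficient for s in sets):
                        continue
                    single = max((r2[tcm_names.index(m)][cell] for m in top
                                  if sig[tcm_names.index(m)][cell]), default=np.nan)
                    comb = fit_multi_tcm(
                        sets, train_frac=cfg.train_frac, cv_folds=cfg.cv_folds,
                        k_max=cfg.k_max, alpha=cfg.alpha, p_value_mode=cfg.p_value_mode,
                        seed=_cell_rng(seed, (97,) + cell))
                    multi_rows.append((reg.region_id, cell, single,
                                       comb.r2_test if comb.significant else np.nan,
                                       comb.significant))
        res.region_top_tcms = region_rank
        res.multi_tcm = pd.DataFrame(
            multi_rows, columns=["region_id", "cell", "best_single_r2",
                                 "combined_r2", "combined_significant"])
        if "lags" not in cfg.stages:
            return res

        # stage: lag profiles per (region, index)
        profiles = []
        gated_cache = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for reg in res.regions:
                for name in tcm_names:
                    rs = []
                    for cell in reg.cells:
                        if cell not in seasons:
                            continue
                        key = (cell, name)
                        if key not in gated_cache:
                            ss = tcm_samples(cell, name)
                            gated_cache[key] = (np.zeros(cfg.max_lag + 1) if ss.insufficient
                                                else gated_correlations(ss, alpha=cfg.alpha))
                        rs.append(gated_cache[key])
                    if rs:
                        profiles.append(build_lag_profile(
                            rs, tcm=name, region_id=reg.region_id,
                            denominator=cfg.lag_denominator))
        res.lag_profiles = profiles
        if "pathways" not in cfg.stages:
            return res

        # stage: mediation pathways over hot-spot cells (or globally)
        med_anom = {}
        if cfg.pathways_scope == "global":
            scope = [(0, c) for c in seasons]
        else:
            scope = [(reg.region_id, cell) for reg in res.regions
                     for cell in reg.cells if cell in seasons]
        fit_frames = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rid, cell in scope:
                season = seasons[cell]
                med_sets = {}
                for mname, grid in self.mediators.items():
                    key = (cell, mname)
                    if key not in med_anom:
                        med_anom[key] = preprocess_series(grid.cell_series(cell), time)
                    med_sets[mname] = build_samples(
                        ba_anom[cell], med_anom[key], time, season,
                        max_lag=cfg.max_lag, min_samples=cfg.min_samples,
                        season_aggregate=cfg.season_aggregate)
                for name in tcm_names:
                    ts = tcm_samples(cell, name)
                    if ts.insufficient:
                        continue
                    for mname, ms in med_sets.items():
                        f = pathway_contribution_frame(
                            ts, ms, tcm=name, mediator=mname,
                            max_total_lag=cfg.max_lag, alpha=cfg.alpha)
                        f.insert(0, "region_id", rid)
                        f.insert(1, "cell", [cell] * len(f))
                        fit_frames.append(f)
        res.pathway_fits = (pd.concat(fit_frames, ignore_index=True) if fit_frames
                            else pd.DataFrame(columns=["region_id", "cell", "tcm", "mediator",
                                                       "i", "j", "contribution"]))
        if len(res.pathway_fits):
            res.contributions = aggregate_contributions(res.pathway_fits)
            res.cell_dominance = per_cell_dominance(res.pathway_fits)
        return res


@dataclass
class TeleconnectionFireResults:
    """Fitted pipeline outputs; see ``summary()`` for the headline numbers."""

    model: TeleconnectionFireModel
    config: PipelineConfig
    seed: int
    seasons: dict
    warnings: list = field(default_factory=list)
    predictability: PredictabilityMap | None = None
    affected_fraction: dict | None = None
    hotspot_map: hs.HotspotMap | None = None
    regions: list | None = None
    region_top_tcms: dict | None = None
    multi_tcm: pd.DataFrame | None = None
    lag_profiles: list | None = None
    pathway_fits: pd.DataFrame | None = None
    contributions: object | None = None
    cell_dominance: pd.DataFrame | None = None

    def region_table(self) -> pd.DataFrame:
        rows = []
        for reg in self.regions or []:
            rows.append((reg.region_id, reg.n_cells, reg.area_fraction,
                         ",".join((self.region_top_tcms or {}).get(reg.region_id, []))))
        return pd.DataFrame(rows, columns=["region_id", "n_cells", "area_fraction", "top_tcms"])

    def lag_profile_frame(self) -> pd.DataFrame:
        if not self.lag_profiles:
            return pd.DataFrame(columns=["region_id", "tcm", "lag", "weight",
                                         "pos_frac", "neg_frac"])
        return pd.concat([p.to_frame() for p in self.lag_profiles], ignore_index=True)

    def summary(self) -> str:
        lines = ["Teleconnection -> burned-area attribution", "=" * 42,
                 f"burnable cells: {int(self.model.mask.sum())}   "
                 f"cells with fire season: {len(self.seasons)}",
                 f"seed: {self.seed}   config: {self.config.digest()}"]
        if self.affected_fraction is not None:
            lines.append("\nPredictable-area fraction (share of burnable cells, p < "
                         f"{self.config.alpha:g}):")
            for k, v in sorted(self.affected_fraction.items(), key=lambda kv: -kv[1]):
                lines.append(f"  {k:>6s}  {100 * v:5.1f}%")
        if self.regions is not None:
            lines.append(f"\nHot spots (Gi* p < 0.01, >= {self.config.min_cells} cells): "
                         f"{len(self.regions)}")
            for _, row in self.region_table().iterrows():
                lines.append(f"  region {row.region_id}: {row.n_cells} cells "
                             f"({100 * row.area_fraction:.1f}% of burnable area); "
                             f"top indices: {row.top_tcms}")
        if self.contributions is not None:
            lines.append("\nDominant mediators (summed pathway contributions):")
            for _, row in self.contributions.dominance.iterrows():
                if row.dominant_mediator is None:
                    continue
                lines.append(f"  region {row.region_id} / {row.tcm}: "
                             f"{row.dominant_mediator} "
                             f"(group: {row.dominant_group_sum} by sum, "
                             f"{row.dominant_group_max} by max)")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, outdir) -> Path:
        """Write stage tables + a manifest (config hash, seed, file hashes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}

        def _write(name, df):
            p = outdir / name
            df.to_csv(p, index=False)
            files[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]

        if self.predictability is not None:
            _write("predictability.csv", self.predictability.to_frame())
            _write("affected_fraction.csv",
                   pd.DataFrame(sorted(self.affected_fraction.items()),
                                columns=["tcm", "fraction"]))
        if self.regions is not None:
            _write("regions.csv", self.region_table())
        if self.multi_tcm is not None:
            _write("multi_tcm.csv", self.multi_tcm)
        if self.lag_profiles is not None:
            _write("lag_profiles.csv", self.lag_profile_frame())
        if self.pathway_fits is not None:
            nz = self.pathway_fits[self.pathway_fits["contribution"] > 0]
            _write("pathway_fits_nonzero.csv", nz)
            if self.contributions is not None:
                _write("contribution_table.csv", self.contributions.by_mediator)
                _write("group_dominance.csv", self.contributions.dominance)
                _write("cell_dominance.csv", self.cell_dominance)
        manifest = {
            "config": asdict(self.config), "config_digest": self.config.digest(),
            "seed": self.seed, "stages_run": list(self.config.stages),
            "skipped": [s for s in ALL_STAGES if s not in self.config.stages],
            "n_cells_with_season": len(self.seasons),
            "n_regions": len(self.regions) if self.regions is not None else None,
            "files": files, "n_warnings": len(self.warnings),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return outdir


def run_pipeline(world_or_paths, config: PipelineConfig | None = None,
                 outdir=None, seed: int | None = None) -> TeleconnectionFireResults:
    """Convenience wrapper: build the model, fit, optionally save artifacts."""
    if isinstance(world_or_paths, World):
        m = TeleconnectionFireModel.from_world(world_or_paths, config)
    else:
        cube_path, indices_path = world_or_paths
        m = TeleconnectionFireModel.from_files(cube_path, indices_path, config)
    res = m.fit(seed=seed)
    if outdir is not None:
        res.save(outdir)
    return res
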