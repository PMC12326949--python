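# telefire

Attribution of monthly burned-area variability to lagged teleconnection
climate modes, and of that influence to weather- versus fuel-mediated
pathways.

Large-scale climate oscillations (ENSO, the Indian Ocean Dipole, the
tropical Atlantic modes, the annular modes, ...) modulate regional fire
activity months to years ahead, either by shaping fire weather (maximum
temperature, potential evaporation, vapour pressure deficit, wind) or by
modulating fuel build-up (NDVI, EVI, FPAR, soil moisture).  `telefire`
implements the full statistical chain needed to detect, localize and
decompose that influence from monthly gridded data, and ships a synthetic
world generator with planted lag/mediation structure so every stage can be
verified against known ground truth without downloading any archive.

The pipeline, per 1°-style grid cell:

1. **Preprocessing** — fire-season peak detection (the three consecutive
   calendar months with the highest accumulated burned area, searched
   circularly so austral DJF seasons are found), removal of the linear
   trend and monthly climatology, and construction of the per-cell sample
   frame pairing fire-season burned-area anomalies with predictors lagged
   0–24 months backward (predictors always coincide with or precede the
   fire month).
2. **PLSR predictability** — partial least squares regression of burned
   area on the 25 lagged copies of one climate index,

       X_j = Σ_t TCM_t · w_tj ,   BA = Σ_{j=1..k} c_j · X_j + ε ,

   with k chosen by 10-fold cross-validation on a 70 % training split and
   predictability reported as the R² between predicted and observed burned
   area on the held-out 30 %.  A cell counts as predictable when the model
   F-test is significant at the 0.05 level.
3. **Hot spots** — Getis-Ord Gi\* z-scores on the per-cell maximum
   predictability field (queen-contiguity weights including self,
   longitude wrap-around), classified into hot/cold tiers at the
   0.10/0.05/0.01 levels; contiguous hot-99 clusters become hot-spot
   regions.
4. **Lag profiles** — per hot spot and index, significance-gated Pearson
   correlations by lag, averaged as absolute values over region cells,
   normalized to peak 1, with positive/negative sign fractions per lag.
5. **Mediation pathways** — for every lag pair (i, j) with i + j ≤ 24, the
   three-step regression chain

       BA = a₁ + b₁·TCM_{i+j} ,   Mediator_j = a₂ + b₂·TCM_{i+j} ,
       BA = a₃ + b₃·Mediator_j ,

   scored as `contribution = R₁²·R₂²` when all three regressions are
   significant (p < 0.05), else 0; contributions are summed over cells and
   lag pairs and compared across the weather and fuel mediator groups
   (group sum and group max) to call the dominant mediator and group per
   hot spot, and cell by cell.

## Worked example

A synthetic 16×16 world with one planted pathway — ENSO drives soil
moisture at a 4-month lag inside a 6×6 region, and soil moisture drives
burned-area anomalies 6 months later:

```python
import numpy as np
from telefire import (PlantedPathway, WorldConfig, generate_world,
                      TeleconnectionFireModel, PipelineConfig)

pathway = PlantedPathway(tcm_index=7, mediator_name="SM",
                         region=((5, 11), (5, 11)),
                         lag_tcm_to_mediator=4, lag_mediator_to_ba=6,
                         strength=2.0)
world = generate_world(WorldConfig(n_years=22, grid_shape=(16, 16),
                                   n_tcms=8, pathway_specs=[pathway], seed=7))
results = TeleconnectionFireModel.from_world(world, PipelineConfig(seed=11)).fit()
print(results.summary())
prof = [p for p in results.lag_profiles
        if p.region_id == 1 and p.tcm == "ENSO"][0]
print("\nENSO lag-profile peak at", int(np.argmax(prof.weight)), "months")
```

prints

```
Teleconnection -> burned-area attribution
==========================================
burnable cells: 256   cells with fire season: 256
seed: 11   config: 060c6b8aeb8cd4ad

Predictable-area fraction (share of burnable cells, p < 0.05):
     Any   42.6%
    ENSO   17.2%
      AO   11.7%
     TSA    6.2%
    EAWR    5.1%
     TNA    5.1%
     POL    4.3%
     IOD    4.3%
     NAO    3.1%

Hot spots (Gi* p < 0.01, >= 5 cells): 1
  region 1: 29 cells (11.3% of burnable area); top indices: ENSO,AO,TSA

Dominant mediators (summed pathway contributions):
  region 1 / AO: SM (group: fuel by sum, fuel by max)
  ...
  region 1 / ENSO: SM (group: fuel by sum, fuel by max)
  ...

ENSO lag-profile peak at 10 months
```

Reading it: ENSO is the most widely predictive index (17.2 % of burnable
cells vs the ~5 % expected by chance for the unrelated modes), the single
Gi\* hot spot overlaps the planted region, the dominant mediator in that
hot spot is the planted soil moisture with the fuel group winning both
dominance rules, and the lag profile peaks at i + j = 10 months — the
planted total lag.  `results.save("out/")` writes the stage tables as CSV
plus a manifest with config hash, seed and per-file content hashes.

The same chain is scriptable from a shell (`telefire simulate`,
`telefire run-all --fixture FX --seed 1 --out OUT`, plus per-stage
subcommands); fixtures travel as CF-like NetCDF cubes, an index CSV and a
JSON config.

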