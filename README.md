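# lurfkit

Land-use random-forest (LURF) modelling of intra-urban NO₂, counterfactual
land-use attribution, and respiratory health-impact propagation — as a
tested, reusable pipeline exercised end-to-end on a synthetic city whose
NO₂-generating process is fully known.

## Who this is for

Urban air-quality and environmental-health researchers who want to

- model fine-scale (200 m) ambient NO₂ from buffer-summarised land-use /
  land-cover (LULC) predictors with a random forest, next to a classical
  land-use regression (LUR) baseline;
- ask counterfactual questions — *how much NO₂ is associated with tree
  canopy, freeways, or high-intensity development?* — by re-predicting the
  surface with a category's predictors set to an NO₂-neutral zero;
- run land-use modification scenarios (±2/5/10 % tree canopy, development,
  freeway traffic) and propagate the NO₂ changes to respiratory-health
  incidence through log-linear concentration–response functions on gridded
  population.

Because field campaigns of this kind are rarely deposited, the package ships
a first-class synthetic-city generator: a 20 × 20 km planar metro area
(freeway corridors, arterial grids, a rail line, an urban core, peripheral
canopy, point emitters, heterogeneous population) with an additive truth
process

```
NO₂(x) = m_season · [ background + Σ_sources sᵢ·Kᵢ(x) − Σ_sinks sᵢ·Kᵢ(x) ]
```

using exponential distance-decay kernels `K(d) = exp(−d/L)` for line and
point sources and local buffer-density kernels for areal cover. Every
downstream stage — buffer extraction, two-phase forest fitting, attribution,
sensitivity, health impacts — can therefore be verified against a known
ground truth. Defaults are calibrated to a dense urban passive-sampler
campaign: 174 summer / 82 winter sites, summer mean ≈ 11 ppb (range 4–23),
winter mean ≈ 13 ppb (range 3–29).

## The model

Each site or grid point is summarised by ~200 predictors: for each of 16
LULC categories and 12 circular buffers (100–1200 m), the buffered area
(ha), road/rail length (km), freeway vehicle-miles (AADT × miles), housing
units, or permitted NOₓ emissions, plus x, y and elevation. Fitting is
two-phase, per season:

1. **Phase 1** — one bagged regression forest on all ~200 columns;
   Strobl-style *conditional* permutation importance (permuting a predictor
   within strata defined by correlated covariates' split points) picks the
   single most informative radius per category, reducing ~200 predictors to
   ~20.
2. **Phase 2** — a systematic (ntree × mtry) sweep over seeds; the model
   with the lowest mean out-of-bag RMSE wins. Forest predictions are
   restricted to the observed training range.

The LUR baseline uses correlation pruning, stepwise AIC with a VIF ceiling,
and k-fold (k = 6) selection. Attribution zeroes one category's columns
everywhere (no rebalancing); modification scenarios change areal cover by
percentage points *of buffer area* with proportional rebalancing of the
other areal categories, clamped to [0, 100] %. Health impacts follow the
log-linear convention Δy = y₀·(1 − e^{−β·ΔC})·Pop.

## Worked example

```python
import lurfkit as lk
from lurfkit.features import extract_features, split_train_validation
from lurfkit.models import phase1_select_buffers, phase2_sweep
from lurfkit.evaluation import compute_metrics
from lurfkit.predict import grid_feature_table, predict_grid, annual_average
from lurfkit.scenarios import attribute_category

params = lk.SyntheticTruthParams(seed=0)
city = lk.generate_city(params)
truth_s = lk.simulate_no2_truth(city, params, "summer")
truth_w = lk.simulate_no2_truth(city, params, "winter")
sites = lk.sample_sites(city, truth_s, truth_w, seed=1)

models = {}
for season, n_val in (("summer", 42), ("winter", 20)):
    obs = sites[sites.season == season].reset_index(drop=True)
    feats = extract_features(obs.rename(columns={"site_id": "location_id"}), city)
    feats["no2_ppb"] = obs["no2_ppb"].to_numpy()
    train, val = split_train_validation(feats, seed=1, n_validation=n_val)
    selected, _ = phase1_select_buffers(train, ntree=300, seed=1)
    result, _ = phase2_sweep(train, selected, ntree_grid=[300], mtry_grid=[4, 8], seeds=[1])
    models[season] = result
    m = compute_metrics(result.predict(val), val["no2_ppb"].to_numpy())
    print(f"{season}: hold-out R2={m.r2:.2f}  RMSE={m.rmse:.2f} ppb  "
          f"NMB={m.normalized_mean_bias:+.1%}  NME={m.normalized_mean_error:.1%}")

grid = grid_feature_table(city, 400.0)
annual = annual_average(
    predict_grid(models["summer"], city, feature_table=grid),
    predict_grid(models["winter"], city, feature_table=grid),
)
print(f"annual surface: mean={annual.valid_values().mean():.1f} ppb, "
      f"range {annual.valid_values().min():.1f}-{annual.valid_values().max():.1f} ppb")
for cat in ("trees", ("freeway", "vmt_freeway"), "dev_high"):
    r = attribute_category(models["summer"], models["winter"], grid, city.extent, cat, 400.0)
    print(f"NO2 attributed to {r.category}: {r.mean_delta_ppb:+.2f} ppb "
          f"(range {r.range_delta_ppb[0]:+.2f} to {r.range_delta_ppb[1]:+.2f})")
```

prints

```
summer: hold-out R2=0.77  RMSE=1.13 ppb  NMB=+3.7%  NME=8.9%
winter: hold-out R2=0.75  RMSE=1.11 ppb  NMB=+2.7%  NME=7.0%
annual surface: mean=10.7 ppb, range 8.3-17.8 ppb
NO2 attributed to trees: -0.27 ppb (range -0.58 to +0.08)
NO2 attributed to freeway+vmt_freeway: +0.24 ppb (range -0.00 to +3.83)
NO2 attributed to dev_high: +0.31 ppb (range -0.05 to +1.51)
```

The hold-out R² near 0.8, the positive freeway/development attributions and
the negative tree-canopy attribution (a few tenths of a ppb averaged over
the study area) are the qualitative signatures this kind of analysis is
expected to produce; here they are recovered from the generator's known
truth process (trees −0.63 ppb, freeway +0.42 ppb on this city), with the
usual random-forest attenuation toward zero.

## Command line

Every stage is also a CLI subcommand over a YAML config
(`lurfkit run-all --config cfg.yaml --out runs/demo --seed 1`; stages:
`generate`, `extract`, `split`, `fit`, `evaluate`, `predict`, `attribute`,
`sensitivity`, `health`). A run directory contains GeoJSON networks, ESRI
ASCII-grid rasters and surfaces, CSV tables and reports, and a
`manifest.json` with stage seeds and output hashes; reruns with the same
config are bit-identical.

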