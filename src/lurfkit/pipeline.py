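"""End-to-end pipeline driver.

Runs the nine analysis stages in order — generate, extract, split, fit,
evaluate, predict, attribute, sensitivity, health — writing every
artifact plus a manifest (stage list, seeds, output hashes) into a run
directory. All randomness derives from a single global seed by fixed
offsets, so a rerun with the same configuration reproduces the
deterministic stages bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as lio
from .categories import ALL_CATEGORIES, DEFAULT_RADII
from .city import (
    SyntheticTruthParams,
    generate_city,
    sample_sites,
    simulate_no2_truth,
)
from .evaluation import compare_surfaces, compute_metrics
from .features import extract_features, split_train_validation
from .grids import write_ascii_grid
from .health import (
    allocate_population,
    apply_hif,
    default_hif_registry,
    worst_quintile_mask,
)
from .models import fit_lur, phase1_select_buffers, phase2_sweep
from .predict import annual_average, grid_feature_table, predict_grid
from .scenarios import Scenario, attribute_category, run_sensitivity

log = logging.getLogger("lurfkit")

STAGES = [
    "generate",
    "extract",
    "split",
    "fit",
    "evaluate",
    "predict",
    "attribute",
    "sensitivity",
    "health",
]

# fixed offsets deriving stage seeds from the global seed
_SEED_OFFSETS = {
    "city": 0,
    "sites": 101,
    "split": 211,
    "phase1": 307,
    "sweep": 401,
    "lur": 503,
}


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; see ``default_config`` for the shipped
    desk-scale defaults."""

    seed: int = 0
    extent_m: float = 20000.0
    lulc_cell_m: float = 50.0
    truth: dict = dataclasses.field(default_factory=dict)  # SyntheticTruthParams overrides
    n_summer: int = 174
    n_winter: int = 82
    n_validation_summer: int = 42
    n_validation_winter: int = 20
    radii: list = dataclasses.field(default_factory=lambda: list(DEFAULT_RADII))
    phase1_ntree: int = 300
    ntree_grid: list = dataclasses.field(default_factory=lambda: [200, 500])
    mtry_grid: list = dataclasses.field(default_factory=lambda: [3, 5, 8])
    sweep_seeds: list = dataclasses.field(default_factory=lambda: [0, 1])
    lur_correlation_threshold: float = 0.7
    lur_vif_ceiling: float = 5.0
    lur_k: int = 6
    grid_cell_m: float = 400.0
    attribution_categories: list = dataclasses.field(
        default_factory=lambda: list(ALL_CATEGORIES)
    )
    scenarios: list = dataclasses.field(
        default_factory=lambda: [
            {"category": c, "delta": d}
            for c in ("vmt_freeway", "trees", "dev_high", "dev_open")
            for d in (-10, -5, -2, 2, 5, 10)
        ]
    )
    health_scenarios: list = dataclasses.field(
        default_factory=lambda: ["vmt_freeway_-10%", "trees_+10%", "trees_+5%", "trees_+2%"]
    )

    def validate(self) -> None:
        if sorted(self.radii) != list(self.radii) or min(self.radii) <= 0:
            raise ValueError("radii must be positive and sorted ascending")
        if self.n_winter > self.n_summer:
            raise ValueError("n_winter must be <= n_summer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = lio.load_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        lio.dump_config(dataclasses.asdict(self), path)


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Executes pipeline stages in order, accumulating artifacts."""

    def __init__(self, config: PipelineConfig, outdir):
        config.validate()
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict = {}
        self.manifest = {
            "seed": config.seed,
            "stage_seeds": {
                k: config.seed + off for k, off in _SEED_OFFSETS.items()
            },
            "stages": [],
            "outputs": {},
        }

    # -- helpers -----------------------------------------------------------

    def _write_csv(self, df: pd.DataFrame, name: str) -> None:
        path = self.outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        self.manifest["outputs"][name] = _sha256(path)

    def _write_surface(self, surface, name: str) -> None:
        path = self.outdir / name
        write_ascii_grid(surface, path)
        self.manifest["outputs"][name] = _sha256(path)

    def _stage(self, name: str, fn) -> None:
        t0 = time.time()
        log.info("stage %s: start", name)
        fn()
        elapsed = time.time() - t0
        self.manifest["stages"].append(
            {"name": name, "status": "complete", "seconds": round(elapsed, 3)}
        )
        log.info("stage %s: complete in %.1fs", name, elapsed)

    def _seed(self, key: str) -> int:
        return self.manifest["stage_seeds"][key]

    # -- stages ------------------------------------------------------------

    def stage_generate(self) -> None:
        cfg = self.config
        params = SyntheticTruthParams(**{**cfg.truth, "seed": self._seed("city")})
        city = generate_city(params, extent_m=cfg.extent_m, lulc_cell_m=cfg.lulc_cell_m)
        truth_s = simulate_no2_truth(city, params, "summer")
        truth_w = simulate_no2_truth(city, params, "winter")
        sites = sample_sites(
            city,
            truth_s,
            truth_w,
            n_summer=cfg.n_summer,
            n_winter=cfg.n_winter,
            noise_sd=params.noise_sd,
            seed=self._seed("sites"),
        )
        lio.write_network_geojson(city.roads, self.outdir / "roads.geojson")
        lio.write_blocks_geojson(city.population_blocks, self.outdir / "population_blocks.geojson")
        lio.write_sites_csv(sites, self.outdir / "sites.csv")
        self._write_surface(truth_s, "truth_summer.asc")
        self._write_surface(truth_w, "truth_winter.asc")
        self.artifacts.update(
            city=city, params=params, truth_summer=truth_s, truth_winter=truth_w, sites=sites
        )

    def stage_extract(self) -> None:
        cfg = self.config
        sites = self.artifacts["sites"]
        city = self.artifacts["city"]
        tables = {}
        for season in ("summer", "winter"):
            sub = sites[sites["season"] == season].reset_index(drop=True)
            locs = sub.rename(columns={"site_id": "location_id"})
            feats = extract_features(locs, city, radii=cfg.radii)
            feats["no2_ppb"] = sub["no2_ppb"].to_numpy()
            tables[season] = feats
            self._write_csv(feats, f"features_{season}.csv")
        self.artifacts["features"] = tables

    def stage_split(self) -> None:
        cfg = self.config
        split = {}
        for season, n_val in (
            ("summer", cfg.n_validation_summer),
            ("winter", cfg.n_validation_winter),
        ):
            train, val = split_train_validation(
                self.artifacts["features"][season],
                seed=self._seed("split"),
                n_validation=n_val,
            )
            split[season] = (train, val)
            self._write_csv(train, f"train_{season}.csv")
            self._write_csv(val, f"validation_{season}.csv")
        self.artifacts["split"] = split

    def stage_fit(self) -> None:
        cfg = self.config
        lurf, lur, selected = {}, {}, {}
        for season in ("summer", "winter"):
            train, _ = self.artifacts["split"][season]
            sel, report = phase1_select_buffers(
                train, ntree=cfg.phase1_ntree, seed=self._seed("phase1")
            )
            selected[season] = sel
            self._write_csv(sel.to_frame(), f"selected_variables_{season}.csv")
            self._write_csv(report.table, f"phase1_importance_{season}.csv")
            res, sweep = phase2_sweep(
                train,
                sel,
                ntree_grid=cfg.ntree_grid,
                mtry_grid=cfg.mtry_grid,
                seeds=[self._seed("sweep") + i for i in range(len(cfg.sweep_seeds))],
            )
            lurf[season] = res
            self._write_csv(sweep, f"sweep_{season}.csv")
            lio.save_forest(res, self.outdir / f"lurf_{season}.json")
            cols = sel.columns()
            lur[season] = fit_lur(
                train["no2_ppb"].to_numpy(),
                train[cols],
                correlation_threshold=cfg.lur_correlation_threshold,
                vif_ceiling=cfg.lur_vif_ceiling,
                k=cfg.lur_k,
                seed=self._seed("lur"),
            )
        self.artifacts.update(lurf=lurf, lur=lur, selected=selected)

    def stage_evaluate(self) -> None:
        rows = []
        for season in ("summer", "winter"):
            _, val = self.artifacts["split"][season]
            obs = val["no2_ppb"].to_numpy()
            for name, res in (
                ("LURF", self.artifacts["lurf"][season]),
                ("LUR", self.artifacts["lur"][season]),
            ):
                m = compute_metrics(res.predict(val), obs)
                row = m.to_frame().iloc[0].to_dict()
                row.update(season=season, model=name)
                if name == "LURF":
                    # the forest's in-sample analogue of goodness of fit:
                    # OOB RMSE and OOB R^2, reported next to the
                    # validation-based figures
                    oob = res.oob_pred
                    y = res.model.endog
                    row["oob_rmse_ppb"] = res.oob_rmse()
                    ok = ~pd.isna(oob)
                    row["oob_r2"] = compute_metrics(oob[ok], y[ok]).r2
                rows.append(row)
        self._write_csv(pd.DataFrame(rows), "metrics.csv")
        self.artifacts["metrics"] = pd.DataFrame(rows)

    def stage_predict(self) -> None:
        cfg = self.config
        city = self.artifacts["city"]
        gf = grid_feature_table(city, cfg.grid_cell_m, radii=cfg.radii)
        self.artifacts["grid_features"] = gf
        surfaces = {}
        for name in ("lurf", "lur"):
            s = predict_grid(self.artifacts[name]["summer"], city, feature_table=gf)
            w = predict_grid(self.artifacts[name]["winter"], city, feature_table=gf)
            a = annual_average(s, w)
            surfaces[name] = {"summer": s, "winter": w, "annual": a}
            for key, surf in surfaces[name].items():
                self._write_surface(surf, f"no2_{name}_{key}.asc")
        self.artifacts["surfaces"] = surfaces
        comp = compare_surfaces(surfaces["lurf"]["annual"], surfaces["lur"]["annual"])
        self._write_csv(comp.to_frame(), "lurf_vs_lur.csv")

    def stage_attribute(self) -> None:
        cfg = self.config
        gf = self.artifacts["grid_features"]
        baseline = self.artifacts["surfaces"]["lurf"]["annual"]
        rows = []
        attr_surfaces = {}
        for cat in cfg.attribution_categories:
            res = attribute_category(
                self.artifacts["lurf"]["summer"],
                self.artifacts["lurf"]["winter"],
                gf,
                self.artifacts["city"].extent,
                cat,
                cell_m=cfg.grid_cell_m,
                baseline=baseline,
            )
            rows.append(res.to_row())
            attr_surfaces[cat] = res.delta_surface
            self._write_surface(res.delta_surface, f"attribution_{cat}.asc")
        self._write_csv(pd.DataFrame(rows), "attribution.csv")
        self.artifacts["attribution"] = attr_surfaces

    def stage_sensitivity(self) -> None:
        cfg = self.config
        scenarios = [Scenario(category=s["category"], delta=s["delta"]) for s in cfg.scenarios]
        table, surfaces = run_sensitivity(
            self.artifacts["lurf"]["summer"],
            self.artifacts["lurf"]["winter"],
            self.artifacts["grid_features"],
            self.artifacts["city"].extent,
            scenarios,
            cell_m=cfg.grid_cell_m,
            baseline=self.artifacts["surfaces"]["lurf"]["annual"],
        )
        self._write_csv(table, "sensitivity.csv")
        for label, surf in surfaces.items():
            self._write_surface(surf, f"sensitivity_{label.replace('%', 'pct')}.asc")
        self.artifacts["sensitivity"] = (table, surfaces)

    def stage_health(self) -> None:
        cfg = self.config
        city = self.artifacts["city"]
        baseline = self.artifacts["surfaces"]["lurf"]["annual"]
        from .city import AGE_BAND_FRACTIONS

        pop_all = allocate_population(city.population_blocks, baseline)
        quintile = worst_quintile_mask(baseline)
        rows = []
        delta_sets = [
            (f"attribution:{cat}", surf)
            for cat, surf in self.artifacts["attribution"].items()
        ]
        _, sens_surfaces = self.artifacts["sensitivity"]
        delta_sets += [
            (f"scenario:{label}", surf)
            for label, surf in sens_surfaces.items()
            if label in cfg.health_scenarios
        ]
        for hif in default_hif_registry():
            frac = AGE_BAND_FRACTIONS.get(hif.age_band, 0.0)
            pop = type(pop_all)(pop_all.values * frac, pop_all.x0, pop_all.y0, pop_all.cell)
            for source, dsurf in delta_sets:
                for scope, mask in (
                    ("study_area", None),
                    ("worst_quintile", quintile),
                ):
                    r = apply_hif(hif, dsurf, pop, scope_mask=mask, scope=scope)
                    row = r.to_row()
                    row["source"] = source
                    rows.append(row)
        self._write_csv(pd.DataFrame(rows), "health.csv")
        self.artifacts["health"] = pd.DataFrame(rows)

    # -- driver ------------------------------------------------------------

    def run(self, through_stage: str = "health") -> dict:
        if through_stage not in STAGES:
            raise ValueError(f"unknown stage {through_stage!r}")
        last = STAGES.index(through_stage)
        for name in STAGES[: last + 1]:
            try:
                self._stage(name, getattr(self, f"stage_{name}"))
            except Exception:
                log.exception("stage %s failed; partial artifacts preserved in %s",
                              name, self.outdir)
                self.manifest["stages"].append({"name": name, "status": "failed"})
                self._write_manifest()
                raise
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def run_pipeline(config: PipelineConfig, outdir, through_stage: str = "health") -> PipelineRun:
    """Run the pipeline; returns the PipelineRun with artifacts in memory."""
    run = PipelineRun(config, outdir)
    run.run(through_stage)
    return run
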