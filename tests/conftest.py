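"""Shared fixtures: the default synthetic city and one fitted pipeline.

Session-scoped because city generation and model fitting dominate test
runtime; every test that needs a fitted model shares this single run.
"""

from __future__ import annotations

import pytest

import lurfkit as lk
from lurfkit.features import extract_features, split_train_validation
from lurfkit.models import phase1_select_buffers, phase2_sweep
from lurfkit.predict import annual_average, grid_feature_table, predict_grid


@pytest.fixture(scope="session")
def default_city():
    params = lk.SyntheticTruthParams(seed=0)
    city = lk.generate_city(params)
    truth_s = lk.simulate_no2_truth(city, params, "summer")
    truth_w = lk.simulate_no2_truth(city, params, "winter")
    return {"params": params, "city": city, "truth_summer": truth_s, "truth_winter": truth_w}


@pytest.fixture(scope="session")
def site_features(default_city):
    """Site observations + per-season feature tables for one seed."""
    city = default_city["city"]
    sites = lk.sample_sites(
        city, default_city["truth_summer"], default_city["truth_winter"], seed=11
    )
    tables = {}
    for season in ("summer", "winter"):
        sub = sites[sites["season"] == season].reset_index(drop=True)
        feats = extract_features(sub.rename(columns={"site_id": "location_id"}), city)
        feats["no2_ppb"] = sub["no2_ppb"].to_numpy()
        tables[season] = feats
    return {"sites": sites, "tables": tables}


@pytest.fixture(scope="session")
def fitted_pipeline(default_city, site_features):
    """Seasonal LURF models + 400 m grid features + baseline surfaces."""
    city = default_city["city"]
    models = {}
    splits = {}
    for season, n_val in (("summer", 42), ("winter", 20)):
        train, val = split_train_validation(
            site_features["tables"][season], seed=7, n_validation=n_val
        )
        splits[season] = (train, val)
        sel, _ = phase1_select_buffers(train, ntree=300, seed=7)
        res, _ = phase2_sweep(
            train, sel, ntree_grid=[300], mtry_grid=[4, 8], seeds=[7]
        )
        models[season] = res
    gf = grid_feature_table(city, 400.0)
    s = predict_grid(models["summer"], city, feature_table=gf)
    w = predict_grid(models["winter"], city, feature_table=gf)
    return {
        "city": city,
        "params": default_city["params"],
        "models": models,
        "splits": splits,
        "grid_features": gf,
        "cell_m": 400.0,
        "summer_surface": s,
        "winter_surface": w,
        "annual_surface": annual_average(s, w),
    }
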