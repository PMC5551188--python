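"""Readers and writers for the pipeline's plain-text artifact formats.

Rasters and surfaces: ESRI ASCII grid (see :mod:`lurfkit.grids`).
Networks, emitters and population blocks: GeoJSON.
Tables (sites, features, reports): CSV.
Configuration: YAML.
Fitted forests: a documented JSON structure of per-tree node arrays.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

__all__ = [
    "read_sites_csv",
    "write_sites_csv",
    "read_feature_table",
    "write_feature_table",
    "write_surface_csv",
    "write_network_geojson",
    "read_network_geojson",
    "write_blocks_geojson",
    "read_blocks_geojson",
    "load_config",
    "dump_config",
    "save_forest",
    "load_forest",
]


# --- site observation tables -------------------------------------------------


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    required = ["site_id", "x", "y", "season", "no2_ppb"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    bad = df[df["no2_ppb"] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive NO2 observation at site_id={bad.iloc[0]['site_id']!r}"
        )
    unknown = set(df["season"]) - {"summer", "winter"}
    if unknown:
        raise ValueError(f"unknown season value(s): {sorted(unknown)}")
    summer = set(df.loc[df["season"] == "summer", "site_id"])
    winter = set(df.loc[df["season"] == "winter", "site_id"])
    if not winter <= summer:
        raise ValueError("winter site ids are not a subset of summer site ids")
    return df


def read_sites_csv(path) -> pd.DataFrame:
    return validate_sites(pd.read_csv(path))


def write_sites_csv(df: pd.DataFrame, path) -> None:
    validate_sites(df)
    df.to_csv(path, index=False, float_format="%.10g")


# --- feature tables ----------------------------------------------------------


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_surface_csv(surface, path) -> None:
    """Export a surface as CSV with columns x, y, value (row-major from
    the south; NaN for no-data cells)."""
    xs = surface.x_centers()
    ys = surface.y_centers()
    rows = {
        "x": np.tile(xs, surface.ny),
        "y": np.repeat(ys, surface.nx),
        "value": surface.values.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# --- GeoJSON -----------------------------------------------------------------


def write_network_geojson(df: pd.DataFrame, path) -> None:
    """Write a line network DataFrame (geometry + attribute columns)."""
    feats = []
    props_cols = [c for c in df.columns if c != "geometry"]
    for _, row in df.iterrows():
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": {c: row[c] for c in props_cols},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_network_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(gj["features"]):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ValueError(f"{path}: malformed geometry in feature {i}") from exc
        rows.append({"geometry": geom, **feat.get("properties", {})})
    return pd.DataFrame(rows)


write_blocks_geojson = write_network_geojson
read_blocks_geojson = read_network_geojson


# --- configuration -----------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# --- fitted forests ----------------------------------------------------------


def save_forest(results, path) -> None:
    """Serialize fitted LURF results to JSON (tree node arrays + metadata)."""
    forest = results.forest
    doc = {
        "format": "lurfkit-forest-v1",
        "ntree": forest.ntree,
        "mtry": forest._mtry,
        "min_split": forest.min_split,
        "seed": forest.seed,
        "exog_names": results.model.exog_names,
        "y_range": list(forest.y_range_),
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "value": t.value.tolist(),
            }
            for t in forest.trees_
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_forest(path):
    """Load serialized LURF results (prediction-capable; no training data)."""
    from .forest import RegressionForest, _Tree
    from .models import LURF, LURFResults

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "lurfkit-forest-v1":
        raise ValueError(f"{path}: not a lurfkit forest file")
    forest = RegressionForest(
        ntree=doc["ntree"], mtry=doc["mtry"], min_split=doc["min_split"], seed=doc["seed"]
    )
    forest._mtry = doc["mtry"]
    forest.trees_ = [
        _Tree(
            np.asarray(t["feature"], dtype=int),
            np.asarray(t["threshold"], dtype=float),
            np.asarray(t["left"], dtype=int),
            np.asarray(t["right"], dtype=int),
            np.asarray(t["value"], dtype=float),
        )
        for t in doc["trees"]
    ]
    forest.y_range_ = tuple(doc["y_range"])
    model = LURF.__new__(LURF)
    model.exog_names = doc["exog_names"]
    model.endog = np.array([np.nan])
    model.exog = np.empty((0, len(doc["exog_names"])))
    return LURFResults(model=model, forest=forest)
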