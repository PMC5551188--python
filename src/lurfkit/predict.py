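"""Applying fitted seasonal models to the prediction grid.

Grid points sit at cell centers of a regular lattice (200 m by default)
in row-major order (south to north); the annual surface is the cellwise
mean of the summer and winter predictions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .city import CityDataset
from .features import SelectedVariables, extract_features
from .grids import GridSurface

__all__ = ["grid_points", "grid_feature_table", "predict_grid", "annual_average", "surface_from_values"]


def grid_points(extent, cell_m: float = 200.0) -> pd.DataFrame:
    """Cell-center prediction points for an extent, row-major from the south."""
    xmin, ymin, xmax, ymax = extent
    nx = int(round((xmax - xmin) / cell_m))
    ny = int(round((ymax - ymin) / cell_m))
    xs = xmin + (np.arange(nx) + 0.5) * cell_m
    ys = ymin + (np.arange(ny) + 0.5) * cell_m
    xx, yy = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {
            "location_id": [f"G{i:06d}" for i in range(nx * ny)],
            "x": xx.ravel(),
            "y": yy.ravel(),
        }
    )


def grid_feature_table(
    city: CityDataset, cell_m: float = 200.0, radii=None
) -> pd.DataFrame:
    """Buffer feature table for every grid point (computed once, reused
    across models, attribution and scenarios)."""
    pts = grid_points(city.extent, cell_m)
    return extract_features(pts, city, radii=radii)


def surface_from_values(values: np.ndarray, extent, cell_m: float) -> GridSurface:
    """Reshape a row-major vector of grid-point values into a surface."""
    xmin, ymin, xmax, ymax = extent
    nx = int(round((xmax - xmin) / cell_m))
    ny = int(round((ymax - ymin) / cell_m))
    return GridSurface(np.asarray(values, dtype=float).reshape(ny, nx), xmin, ymin, cell_m)


def predict_grid(
    results,
    city: CityDataset,
    selected: SelectedVariables | None = None,
    cell_m: float = 200.0,
    feature_table: pd.DataFrame | None = None,
) -> GridSurface:
    """Apply a fitted seasonal model (LURF or LUR results) to the grid.

    ``feature_table`` may be a precomputed :func:`grid_feature_table`;
    otherwise features are extracted at the radii the model needs.
    """
    if feature_table is None:
        if selected is None:
            selected = getattr(results, "selected", None)
        radii = sorted(set(selected.radii.values())) if selected else None
        feature_table = grid_feature_table(city, cell_m, radii=radii)
    else:
        cell_m = _infer_cell(feature_table, city.extent)
    pred = results.predict(feature_table)
    return surface_from_values(pred, city.extent, cell_m)


def _infer_cell(feature_table: pd.DataFrame, extent) -> float:
    xmin, ymin, xmax, ymax = extent
    xs = np.unique(feature_table["x"].to_numpy())
    cell = float(xs[1] - xs[0]) if xs.size > 1 else float(xmax - xmin)
    n_expected = round((xmax - xmin) / cell) * round((ymax - ymin) / cell)
    if n_expected != len(feature_table):
        raise ValueError("feature table does not cover the full grid")
    return cell


def annual_average(summer: GridSurface, winter: GridSurface) -> GridSurface:
    """Cellwise mean of the two seasonal surfaces (NaN propagates)."""
    if not summer.same_geometry(winter):
        raise ValueError("seasonal surface geometry mismatch")
    return GridSurface(
        0.5 * (summer.values + winter.values), summer.x0, summer.y0, summer.cell
    )
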