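"""Buffer-based land-use feature extraction.

Each location (monitoring site or prediction grid point) is summarised
by ~200 predictors: for every land-use category and every circular
buffer radius (100-1200 m by default), the amount of that category
inside the buffer disc, plus the point features x, y and elevation.

Conventions
-----------
- Areal categories: buffered area in hectares. A raster cell contributes
  ``cell_area * fraction`` when its center lies inside the disc; buffers
  are clipped at the study extent without renormalisation.
- Road classes and rail: line length inside the disc, km (closed-form
  chord clipping per segment).
- vmt_freeway: sum over freeway segments of AADT x miles inside the
  disc (vehicle-miles/day).
- housing: unit count inside the disc; emissions: permitted NOx
  tons/year summed over point emitters inside the disc.
- The "trees" category is the sum of the deciduous, evergreen and mixed
  sub-layers when those are supplied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    ALL_CATEGORIES,
    AREAL_CATEGORIES,
    DEFAULT_RADII,
    LINE_CATEGORIES,
    METERS_PER_MILE,
    feature_column,
)
from .city import CityDataset
from .geometry import length_in_disc

__all__ = [
    "extract_features",
    "split_train_validation",
    "SelectedVariables",
    "feature_columns",
    "buffer_area_ha",
]

_CHUNK = 256


def feature_columns(radii=None, categories=None) -> list[str]:
    """Deterministic buffer-feature column order: categories alphabetical,
    radii ascending."""
    radii = sorted(radii or DEFAULT_RADII)
    categories = sorted(categories or ALL_CATEGORIES)
    return [feature_column(c, r) for c in categories for r in radii]


def buffer_area_ha(radius_m: float) -> float:
    """Area of the buffer disc in hectares."""
    return np.pi * radius_m**2 / 1e4


@dataclass
class SelectedVariables:
    """One chosen buffer radius per category, plus the point features."""

    radii: dict  # category -> radius (m)
    degenerate: set = field(default_factory=set)  # all-zero categories
    include_xy: bool = True
    include_elevation: bool = True

    def columns(self) -> list[str]:
        cols = [feature_column(c, r) for c, r in sorted(self.radii.items())]
        if self.include_xy:
            cols += ["x", "y"]
        if self.include_elevation:
            cols += ["elevation"]
        return cols

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": sorted(self.radii),
                "radius_m": [self.radii[c] for c in sorted(self.radii)],
                "degenerate": [c in self.degenerate for c in sorted(self.radii)],
            }
        )


def _areal_stack(city: CityDataset):
    """(layer names, stacked values) for areal categories + housing counts."""
    names = list(AREAL_CATEGORIES) + ["housing"]
    ref = city.elevation
    stack = np.empty((len(names), ref.ny, ref.nx))
    for i, name in enumerate(names):
        if name == "housing":
            stack[i] = city.housing.values
        else:
            stack[i] = city.areal_fraction(name).values
    return names, stack


def extract_features(
    locations: pd.DataFrame,
    city: CityDataset,
    radii=None,
) -> pd.DataFrame:
    """Build the buffer feature table for a set of locations.

    ``locations`` needs columns ``location_id``, ``x``, ``y``.
    Returns a DataFrame with columns location_id, x, y, elevation, then
    the buffer features in deterministic order.
    """
    radii = sorted(radii or DEFAULT_RADII)
    if any(r <= 0 for r in radii):
        raise ValueError("buffer radii must be positive")
    x = locations["x"].to_numpy(dtype=float)
    y = locations["y"].to_numpy(dtype=float)
    xmin, ymin, xmax, ymax = city.extent
    margin = max(radii)
    bad = (x < xmin - margin) | (x > xmax + margin) | (y < ymin - margin) | (y > ymax + margin)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} location(s) outside the study extent plus the "
            f"maximum buffer radius margin"
        )
    nloc = x.size
    out = {}

    # --- areal + housing via padded windowed raster sums ------------------
    names, stack = _areal_stack(city)
    ref = city.elevation
    cell = ref.cell
    cell_ha = (cell / 100.0) ** 2
    m = int(np.ceil(max(radii) / cell))
    padded = np.pad(stack, ((0, 0), (m, m), (m, m)))
    row, col = ref.cell_index(x, y)
    # offset of each location from its containing cell center
    bdx = ref.x0 + (col + 0.5) * cell - x
    bdy = ref.y0 + (row + 0.5) * cell - y
    off = np.arange(-m, m + 1) * cell
    w = 2 * m + 1
    sums = np.zeros((nloc, len(names), len(radii)))
    r2 = np.array(radii, dtype=float) ** 2
    for start in range(0, nloc, _CHUNK):
        sl = slice(start, min(start + _CHUNK, nloc))
        rows = row[sl]
        cols = col[sl]
        nc = rows.size
        # gather uniform windows from the padded stack
        ridx = rows[:, None] + np.arange(w)[None, :]  # (nc, w) into padded rows
        cidx = cols[:, None] + np.arange(w)[None, :]
        win = padded[:, ridx[:, :, None], cidx[:, None, :]]  # (nlayer, nc, w, w)
        d2 = (bdy[sl][:, None] + off[None, :]) ** 2
        d2 = d2[:, :, None] + ((bdx[sl][:, None] + off[None, :]) ** 2)[:, None, :]
        for k, rr2 in enumerate(r2):
            mask = (d2 <= rr2).astype(float)  # (nc, w, w)
            sums[sl, :, k] = np.einsum("lcij,cij->cl", win, mask)
    for i, name in enumerate(names):
        for k, r in enumerate(radii):
            if name == "housing":
                out[feature_column(name, r)] = sums[:, i, k]
            else:
                out[feature_column(name, r)] = sums[:, i, k] * cell_ha

    # --- line networks and freeway VMT ------------------------------------
    for cls in LINE_CATEGORIES:
        seg = city.class_segments(cls)
        for r in radii:
            if len(seg) == 0:
                out[feature_column(cls, r)] = np.zeros(nloc)
                if cls == "freeway":
                    out[feature_column("vmt_freeway", r)] = np.zeros(nloc)
                continue
            lens = length_in_disc(x, y, float(r), seg)  # (nloc, nseg) metres
            out[feature_column(cls, r)] = lens.sum(axis=1) / 1000.0
            if cls == "freeway":
                out[feature_column("vmt_freeway", r)] = (
                    lens / METERS_PER_MILE * seg.attr
                ).sum(axis=1)

    # --- point emitters ----------------------------------------------------
    ex = city.emitters["x"].to_numpy()
    ey = city.emitters["y"].to_numpy()
    nox = city.emitters["nox_tons_per_year"].to_numpy()
    d = np.hypot(x[:, None] - ex, y[:, None] - ey) if len(ex) else np.empty((nloc, 0))
    for r in radii:
        out[feature_column("emissions", r)] = (
            ((d <= r) * nox).sum(axis=1) if len(ex) else np.zeros(nloc)
        )

    head = {
        "location_id": locations["location_id"].to_numpy(),
        "x": x,
        "y": y,
        "elevation": city.elevation.sample(x, y),
    }
    return pd.DataFrame({**head, **{c: out[c] for c in feature_columns(radii)}})


def split_train_validation(
    table: pd.DataFrame,
    fraction: float = 0.25,
    seed: int = 0,
    n_validation: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation split, fixed before fitting.

    ``n_validation`` overrides ``fraction`` with an explicit hold-out
    count (e.g. 42 of 174 summer sites, 20 of 82 winter sites).
    """
    n = len(table)
    if n < 8:
        raise ValueError("fewer than 8 observations: split is meaningless")
    if n_validation is None:
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        n_validation = int(round(fraction * n))
    if not 0 < n_validation < n:
        raise ValueError("validation count must be in (0, n)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = np.sort(perm[:n_validation])
    train_idx = np.sort(perm[n_validation:])
    return table.iloc[train_idx].reset_index(drop=True), table.iloc[val_idx].reset_index(drop=True)
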