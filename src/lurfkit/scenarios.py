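"""Counterfactual attribution and land-use modification scenarios.

Attribution replaces one land-use category with an NO2-neutral land use
by zeroing its predictor columns everywhere (no rebalancing), and takes
the difference between the baseline annual surface and the
category-zeroed annual surface.

The sensitivity engine instead *modifies* a category: areal categories
change by a signed number of percentage points of the buffer area (so a
+2% change raises cover even where there currently is none), with the
other areal categories proportionately rebalanced so the areal total is
preserved where possible, and everything clamped to [0, 100]%. Freeway
VMT scenarios scale the vehicle-miles columns multiplicatively and
rebalance nothing.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import AREAL_CATEGORIES, parse_feature_column
from .features import buffer_area_ha
from .grids import GridSurface
from .predict import annual_average, surface_from_values

__all__ = [
    "Scenario",
    "AttributionResult",
    "zero_category",
    "apply_modification",
    "attribute_category",
    "run_sensitivity",
]

DEFAULT_DELTAS = (-10.0, -5.0, -2.0, 2.0, 5.0, 10.0)


@dataclass
class Scenario:
    """A study-area-wide land-use change.

    ``delta`` is in percentage points of buffer area for areal
    categories, and in relative percent for ``vmt_freeway``.
    """

    category: str
    kind: str = "modify"  # 'modify' or 'zero'
    delta: float | None = None
    rebalance: bool = True

    def __post_init__(self):
        if self.kind not in ("modify", "zero"):
            raise ValueError("scenario kind must be 'modify' or 'zero'")
        if self.kind == "modify" and self.delta is None:
            raise ValueError("modify scenarios need a delta")
        if self.kind == "zero":
            self.delta = None

    @property
    def label(self) -> str:
        if self.kind == "zero":
            return f"{self.category}_zero"
        return f"{self.category}_{self.delta:+g}%"


@dataclass
class AttributionResult:
    """NO2 attributed to one category (baseline minus category-zeroed)."""

    category: str
    delta_surface: GridSurface
    mean_delta_ppb: float
    range_delta_ppb: tuple

    def to_row(self) -> dict:
        return {
            "category": self.category,
            "mean_delta_ppb": self.mean_delta_ppb,
            "min_delta_ppb": self.range_delta_ppb[0],
            "max_delta_ppb": self.range_delta_ppb[1],
        }


def _category_columns(table: pd.DataFrame, category: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(f"{category}_")]
    cols = [c for c in cols if parse_feature_column(c)[0] == category]
    if not cols:
        raise KeyError(f"category {category!r} has no columns in the feature table")
    return cols


def zero_category(table: pd.DataFrame, category: str) -> pd.DataFrame:
    """Set every buffer column of one category to zero; touch nothing else."""
    cols = _category_columns(table, category)
    out = table.copy()
    out[cols] = 0.0
    return out


def apply_modification(table: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Apply a modification scenario to a buffer feature table.

    Areal categories: at every radius, the target category's cover (as a
    percentage of the buffer disc area) changes by ``delta`` percentage
    points, clamped to [0, 100]; the other areal categories at the same
    radius are scaled by a common factor so the areal total is preserved
    where possible, each clamped to remain non-negative.
    ``vmt_freeway``: all VMT columns are multiplied by (1 + delta/100).
    """
    if scenario.kind == "zero":
        return zero_category(table, scenario.category)
    cat = scenario.category
    delta = float(scenario.delta)
    out = table.copy()
    if cat == "vmt_freeway":
        cols = _category_columns(table, cat)
        out[cols] = table[cols].to_numpy() * (1.0 + delta / 100.0)
        return out
    if cat not in AREAL_CATEGORIES:
        raise ValueError(
            f"modification scenarios apply to areal categories or 'vmt_freeway', got {cat!r}"
        )
    target_cols = _category_columns(table, cat)
    other_cats = [c for c in AREAL_CATEGORIES if c != cat]
    warned = False
    for col in target_cols:
        _, r = parse_feature_column(col)
        area = buffer_area_ha(r)
        pct = table[col].to_numpy() / area * 100.0
        new_pct = np.clip(pct + delta, 0.0, 100.0)
        out[col] = new_pct / 100.0 * area
        if not scenario.rebalance:
            continue
        ocols = [c for c in (f"{oc}_{r:04d}" for oc in other_cats) if c in table.columns]
        if not ocols:
            continue
        opct = table[ocols].to_numpy() / area * 100.0
        osum = opct.sum(axis=1)
        total = pct + osum
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (total - new_pct) / osum
        f = np.where(osum > 0, np.clip(f, 0.0, None), 0.0)
        empty_pool = (osum <= 0) & (delta > 0)
        if empty_pool.any() and not warned:
            warnings.warn(
                "rebalancing pool empty at some locations for a positive delta; "
                "target clamped, nothing rebalanced there"
            )
            warned = True
        new_opct = np.clip(opct * f[:, None], 0.0, 100.0)
        for j, oc in enumerate(ocols):
            out[oc] = new_opct[:, j] / 100.0 * area
    return out


def _annual_from_table(results_s, results_w, table: pd.DataFrame, extent, cell_m: float) -> GridSurface:
    s = surface_from_values(results_s.predict(table), extent, cell_m)
    w = surface_from_values(results_w.predict(table), extent, cell_m)
    return annual_average(s, w)


def attribute_category(
    results_s,
    results_w,
    grid_features: pd.DataFrame,
    extent,
    category,
    cell_m: float,
    baseline: GridSurface | None = None,
) -> AttributionResult:
    """Annual NO2 attributed to ``category`` (a name, or a sequence of
    names zeroed jointly)."""
    cats = [category] if isinstance(category, str) else list(category)
    if baseline is None:
        baseline = _annual_from_table(results_s, results_w, grid_features, extent, cell_m)
    zeroed = grid_features
    for c in cats:
        zeroed = zero_category(zeroed, c)
    counterfactual = _annual_from_table(results_s, results_w, zeroed, extent, cell_m)
    delta = GridSurface(
        baseline.values - counterfactual.values, baseline.x0, baseline.y0, baseline.cell
    )
    v = delta.valid_values()
    return AttributionResult(
        category="+".join(cats),
        delta_surface=delta,
        mean_delta_ppb=float(v.mean()),
        range_delta_ppb=(float(v.min()), float(v.max())),
    )


def run_sensitivity(
    results_s,
    results_w,
    grid_features: pd.DataFrame,
    extent,
    scenarios,
    cell_m: float,
    baseline: GridSurface | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate modification scenarios against the baseline annual surface.

    Returns a summary table (mean study-wide %dNO2, maximum local |%dNO2|,
    mean dNO2 in ppb) and the per-scenario delta surfaces.
    """
    if baseline is None:
        baseline = _annual_from_table(results_s, results_w, grid_features, extent, cell_m)
    rows = []
    surfaces = {}
    for sc in scenarios:
        modified = apply_modification(grid_features, sc)
        mod_surface = _annual_from_table(results_s, results_w, modified, extent, cell_m)
        delta = GridSurface(
            mod_surface.values - baseline.values, baseline.x0, baseline.y0, baseline.cell
        )
        pct = 100.0 * delta.values / baseline.values
        ok = np.isfinite(pct)
        rows.append(
            {
                "scenario": sc.label,
                "category": sc.category,
                "delta": sc.delta,
                "mean_pct_change": float(pct[ok].mean()),
                "max_local_abs_pct_change": float(np.abs(pct[ok]).max()),
                "mean_delta_ppb": float(delta.values[ok].mean()),
            }
        )
        surfaces[sc.label] = delta
    columns = [
        "scenario",
        "category",
        "delta",
        "mean_pct_change",
        "max_local_abs_pct_change",
        "mean_delta_ppb",
    ]
    return pd.DataFrame(rows, columns=columns), surfaces
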