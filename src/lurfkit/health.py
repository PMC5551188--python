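"""Health impact propagation: from delta-NO2 surfaces to incidence.

Concentration-response follows the log-linear convention used by
benefits-mapping tools for respiratory endpoints:

    dy = y0 * (1 - exp(-beta * dC)) * Pop

per cell, where y0 is the baseline incidence (cases per person per
year), beta the concentration-response coefficient per ppb, dC the NO2
change in ppb (positive = the scenario or category adds NO2) and Pop
the cell population in the endpoint's age band. For small beta*dC this
reduces to the linear y0*beta*dC*Pop.

The shipped endpoint registry mirrors the structure of standard
respiratory endpoint tables (asthma exacerbation in school-age
children, cough, asthma ER visits and respiratory hospital admissions
in the elderly); its beta/y0 values are synthetic stand-in
configuration, clearly labelled, not published coefficients.

Population reaches the grid by areal weighting: each source polygon's
count is split across cells in proportion to overlap area, conserving
the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grids import GridSurface, Raster

__all__ = [
    "HealthImpactFunction",
    "HealthImpactResult",
    "default_hif_registry",
    "allocate_population",
    "apply_hif",
    "worst_quintile_mask",
]


@dataclass
class HealthImpactFunction:
    endpoint: str
    age_band: str  # key into the population raster dict
    beta_per_ppb: float
    baseline_incidence: float  # cases per person per year
    form: str = "log-linear"

    def __post_init__(self):
        if not np.isfinite(self.beta_per_ppb):
            raise ValueError("beta must be finite")
        if self.baseline_incidence < 0:
            raise ValueError("baseline incidence must be >= 0")


def default_hif_registry() -> list[HealthImpactFunction]:
    """Synthetic stand-in endpoint registry (structure mirrors standard
    respiratory tables; coefficients are package configuration, not
    published values)."""
    return [
        HealthImpactFunction("asthma_exacerbation_missed_school_days", "4-12", 0.010, 0.50),
        HealthImpactFunction("asthma_exacerbation_one_or_more_symptoms", "4-12", 0.012, 1.20),
        HealthImpactFunction("cough", "7-14", 0.008, 0.50),
        HealthImpactFunction("er_visits_asthma", "75+", 0.004, 0.002),
        HealthImpactFunction("hospital_admissions_all_respiratory", "65+", 0.003, 0.015),
    ]


@dataclass
class HealthImpactResult:
    endpoint: str
    age_band: str
    scope: str  # 'study_area' or 'worst_quintile'
    delta_cases: Raster  # per-cell d-incidence, cases/year
    total_delta_cases: float
    population: float
    rate_per_100k: float

    def to_row(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "age_band": self.age_band,
            "scope": self.scope,
            "delta_cases_per_year": self.total_delta_cases,
            "population": self.population,
            "rate_per_100000": self.rate_per_100k,
        }


def allocate_population(blocks: pd.DataFrame, grid: Raster) -> Raster:
    """Areal-weighting allocation of polygon counts onto a grid.

    ``blocks`` needs columns ``geometry`` (shapely polygons) and
    ``population``. Each polygon's count is split across grid cells in
    proportion to the polygon/cell overlap area; totals are conserved
    (up to the part of a polygon lying outside the grid).
    """
    if (blocks["population"] < 0).any():
        raise ValueError("negative population count in source polygons")
    out = np.zeros((grid.ny, grid.nx))
    cell = grid.cell
    for geom, count in zip(blocks["geometry"], blocks["population"]):
        if count == 0 or geom.is_empty:
            continue
        area = geom.area
        if area <= 0:
            continue
        bxmin, bymin, bxmax, bymax = geom.bounds
        c0 = max(0, int(np.floor((bxmin - grid.x0) / cell)))
        c1 = min(grid.nx, int(np.ceil((bxmax - grid.x0) / cell)))
        r0 = max(0, int(np.floor((bymin - grid.y0) / cell)))
        r1 = min(grid.ny, int(np.ceil((bymax - grid.y0) / cell)))
        for r in range(r0, r1):
            for c in range(c0, c1):
                cell_box = box(
                    grid.x0 + c * cell,
                    grid.y0 + r * cell,
                    grid.x0 + (c + 1) * cell,
                    grid.y0 + (r + 1) * cell,
                )
                ov = geom.intersection(cell_box).area
                if ov > 0:
                    out[r, c] += count * ov / area
    return Raster(out, grid.x0, grid.y0, cell)


def apply_hif(
    hif: HealthImpactFunction,
    delta_surface: GridSurface,
    population: Raster,
    scope_mask: np.ndarray | None = None,
    scope: str = "study_area",
) -> HealthImpactResult:
    """Propagate a dNO2 surface through one health impact function."""
    if not delta_surface.same_geometry(population):
        raise ValueError("delta surface and population raster geometry mismatch")
    dC = np.nan_to_num(delta_surface.values, nan=0.0)
    dy = hif.baseline_incidence * (1.0 - np.exp(-hif.beta_per_ppb * dC)) * population.values
    if scope_mask is None:
        scope_mask = np.ones_like(dy, dtype=bool)
    total = float(dy[scope_mask].sum())
    pop = float(population.values[scope_mask].sum())
    rate = 1e5 * total / pop if pop > 0 else float("nan")
    return HealthImpactResult(
        endpoint=hif.endpoint,
        age_band=hif.age_band,
        scope=scope,
        delta_cases=Raster(dy, population.x0, population.y0, population.cell),
        total_delta_cases=total,
        population=pop,
        rate_per_100k=rate,
    )


def worst_quintile_mask(surface: GridSurface) -> np.ndarray:
    """Mask of cells at or above the 80th percentile of the surface.

    A constant surface yields a whole-area mask with a warning.
    """
    vals = surface.valid_values()
    if vals.size < 5:
        raise ValueError("need at least 5 valid cells for a quintile mask")
    if vals.max() == vals.min():
        warnings.warn("constant surface: worst-quintile mask covers the whole area")
        return surface.mask.copy()
    thr = np.percentile(vals, 80.0)
    return surface.mask & (surface.values >= thr)
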