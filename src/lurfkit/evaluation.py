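"""Model performance metrics and surface-to-surface comparison.

Normalised mean bias and error follow the air-quality convention of
averaging per-observation relative deviations:

    NMB = (1/N) sum (mod_i - obs_i) / obs_i
    NME = (1/N) sum |mod_i - obs_i| / obs_i

R^2 on hold-out data is reported as the squared Pearson correlation
(the 1 - SS_res/SS_tot variant is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSurface

__all__ = ["MetricsReport", "ComparisonReport", "compute_metrics", "compare_surfaces"]


@dataclass
class MetricsReport:
    n: int
    r2: float  # squared Pearson correlation (NaN if undefined)
    r2_ss: float  # 1 - SS_res/SS_tot variant
    normalized_mean_bias: float
    normalized_mean_error: float
    rmse: float
    mae: float
    r2_undefined: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [self.n],
                "r2": [self.r2],
                "r2_ss": [self.r2_ss],
                "normalized_mean_bias": [self.normalized_mean_bias],
                "normalized_mean_error": [self.normalized_mean_error],
                "rmse_ppb": [self.rmse],
                "mae_ppb": [self.mae],
            }
        )


def compute_metrics(modeled, observed) -> MetricsReport:
    """Metrics of a modelled series against observations (both ppb)."""
    mod = np.asarray(modeled, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if mod.shape != obs.shape:
        raise ValueError("modeled and observed must have equal length")
    bad = np.where(obs <= 0)[0]
    if bad.size:
        raise ValueError(
            f"observed NO2 must be positive; offending record index {int(bad[0])} "
            f"(value {obs[bad[0]]!r})"
        )
    diff = mod - obs
    nmb = float(np.mean(diff / obs))
    nme = float(np.mean(np.abs(diff) / obs))
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    undefined = obs.std() == 0 or mod.std() == 0
    if undefined:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(mod, obs)[0, 1] ** 2)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2_ss = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(diff**2)) / ss_tot
    return MetricsReport(
        n=mod.size,
        r2=r2,
        r2_ss=r2_ss,
        normalized_mean_bias=nmb,
        normalized_mean_error=nme,
        rmse=rmse,
        mae=mae,
        r2_undefined=bool(undefined),
    )


@dataclass
class ComparisonReport:
    """Pairwise comparison of surface A against surface B."""

    n: int
    pearson_r: float
    slope: float
    intercept: float
    adj_r2: float
    normalized_mean_bias: float  # of A relative to B
    normalized_mean_error: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: [v] for k, v in self.__dict__.items()})


def compare_surfaces(a: GridSurface, b: GridSurface) -> ComparisonReport:
    """Compare two surfaces cell-by-cell (NaN cells excluded pairwise)."""
    if not a.same_geometry(b):
        raise ValueError("surface geometry mismatch")
    ok = a.mask & b.mask
    if not ok.any():
        raise ValueError("no jointly valid cells")
    av = a.values[ok]
    bv = b.values[ok]
    n = av.size
    r = float(np.corrcoef(av, bv)[0, 1]) if av.std() > 0 and bv.std() > 0 else float("nan")
    # least-squares line mapping B -> A
    X = np.column_stack([np.ones(n), bv])
    beta, *_ = np.linalg.lstsq(X, av, rcond=None)
    pred = X @ beta
    ss_res = float(np.sum((av - pred) ** 2))
    ss_tot = float(np.sum((av - av.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    if (bv <= 0).any():
        nmb = nme = float("nan")
    else:
        nmb = float(np.mean((av - bv) / bv))
        nme = float(np.mean(np.abs(av - bv) / bv))
    return ComparisonReport(
        n=n,
        pearson_r=r,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        adj_r2=float(adj_r2),
        normalized_mean_bias=nmb,
        normalized_mean_error=nme,
    )
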