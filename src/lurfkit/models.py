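"""Seasonal NO2 models: the land-use random forest (LURF) and the
classical land-use regression (LUR) baseline.

The modelling surface follows the statsmodels convention: a model object
is built from data, ``fit`` returns a results object carrying the
estimates, diagnostics and a ``summary()`` table, and prediction hangs
off the results object.

The LURF procedure has two phases. Phase 1 fits one forest on the full
~200-column buffer table and, for each land-use category, keeps the
buffer radius whose variable has the highest conditional permutation
importance — reducing ~200 candidate predictors to ~20 (one radius per
category plus x, y and elevation). Phase 2 sweeps the (ntree, mtry)
hyperparameter grid over a set of seeds and selects the combination with
the lowest mean out-of-bag RMSE (ties toward smaller ntree, then smaller
mtry). LURF predictions are restricted to the training response range.

The LUR baseline prunes correlated predictors, runs a stepwise AIC
search retaining up to four candidate models that pass a VIF ceiling,
and picks the final model by k-fold (k=6) cross-validated RMSE.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .categories import parse_feature_column
from .features import SelectedVariables
from .forest import ImportanceReport, RegressionForest, permutation_importance

__all__ = [
    "LURF",
    "LURFResults",
    "LUR",
    "LURResults",
    "phase1_select_buffers",
    "phase2_sweep",
    "fit_lur",
    "PAPER_NTREE_GRID",
    "PAPER_MTRY_GRID",
]

#: Hyperparameter grids explored for the "robust" forest.
PAPER_NTREE_GRID = (500, 1000, 2000, 3000, 4000, 5000)
PAPER_MTRY_GRID = (1, 2, 3, 4, 5, 6, 7, 8)


def _as_xy(exog) -> tuple[np.ndarray, list[str]]:
    if isinstance(exog, pd.DataFrame):
        return exog.to_numpy(dtype=float), list(exog.columns)
    exog = np.asarray(exog, dtype=float)
    return exog, [f"x{j}" for j in range(exog.shape[1])]


class LURF:
    """Land-use random forest model of seasonal NO2.

    Parameters
    ----------
    endog : array-like, observed NO2 (ppb)
    exog : DataFrame or array of buffer/point predictors
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog, self.exog_names = _as_xy(exog)
        if self.endog.size < 10:
            raise ValueError("need at least 10 observations")
        if self.endog.size != self.exog.shape[0]:
            raise ValueError("endog/exog length mismatch")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, response: str = "no2_ppb", columns=None):
        cols = columns or [
            c for c in table.columns if c not in ("location_id", "site_id", response)
        ]
        return cls(table[response], table[cols])

    def fit(self, ntree: int = 500, mtry: int | None = None, seed: int = 0) -> "LURFResults":
        forest = RegressionForest(ntree=ntree, mtry=mtry, seed=seed)
        if np.all(self.endog == self.endog[0]):
            warnings.warn("constant response: forest degenerates to single-leaf trees")
        forest.fit(self.exog, self.endog)
        return LURFResults(self, forest)


@dataclass
class LURFResults:
    """Fitted LURF: the forest, its OOB diagnostics and bounded predict."""

    model: LURF
    forest: RegressionForest
    selected: SelectedVariables | None = None
    sweep_table: pd.DataFrame | None = None

    @property
    def ntree(self) -> int:
        return self.forest.ntree

    @property
    def mtry(self) -> int:
        return self.forest._mtry

    @property
    def seed(self) -> int:
        return self.forest.seed

    @property
    def response_range(self) -> tuple[float, float]:
        return self.forest.y_range_

    @property
    def oob_pred(self) -> np.ndarray:
        return self.forest.oob_predictions()

    def oob_rmse(self) -> float:
        return self.forest.oob_rmse()

    def predict(self, exog) -> np.ndarray:
        """Predict NO2, restricted to the observed training range."""
        if isinstance(exog, pd.DataFrame):
            exog = exog[self.model.exog_names].to_numpy(dtype=float)
        pred = self.forest.predict(exog)
        lo, hi = self.response_range
        return np.clip(pred, lo, hi)

    def importance(self, mode: str = "conditional", seed: int = 0, **kw) -> ImportanceReport:
        return permutation_importance(
            self.forest, mode=mode, seed=seed, variable_names=self.model.exog_names, **kw
        )

    def summary(self) -> str:
        lo, hi = self.response_range
        lines = [
            "Land-Use Random Forest results",
            "=" * 38,
            f"n obs            {self.model.endog.size}",
            f"predictors       {len(self.model.exog_names)}",
            f"ntree            {self.ntree}",
            f"mtry             {self.mtry}",
            f"seed             {self.seed}",
            f"OOB RMSE (ppb)   {self.oob_rmse():.3f}",
            f"response range   [{lo:.2f}, {hi:.2f}] ppb (predictions clipped)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Phase 1: buffer-radius selection
# ---------------------------------------------------------------------------


def phase1_select_buffers(
    table: pd.DataFrame,
    response: str = "no2_ppb",
    ntree: int = 300,
    mtry: int | None = None,
    seed: int = 0,
    correlation_threshold: float = 0.2,
    max_conditioning: int = 20,
) -> tuple[SelectedVariables, ImportanceReport]:
    """Pick, per category, the most important buffer radius.

    One forest is fitted on every buffer column; conditional permutation
    importance ranks the radii within each category. Categories whose
    columns are identically zero are flagged degenerate and assigned the
    smallest radius.
    """
    buffer_cols = [
        c
        for c in table.columns
        if c not in ("location_id", "site_id", "x", "y", "elevation", response)
    ]
    model = LURF(table[response], table[buffer_cols])
    res = model.fit(ntree=ntree, mtry=mtry, seed=seed)
    report = res.importance(
        mode="conditional",
        seed=seed,
        correlation_threshold=correlation_threshold,
        max_conditioning=max_conditioning,
    )
    imp = report.table.set_index("variable")["raw"]
    radii: dict[str, int] = {}
    degenerate: set[str] = set()
    by_cat: dict[str, list[int]] = {}
    for c in buffer_cols:
        cat, r = parse_feature_column(c)
        by_cat.setdefault(cat, []).append(r)
    for cat, rs in by_cat.items():
        rs = sorted(rs)
        cols = [f"{cat}_{r:04d}" for r in rs]
        if np.allclose(table[cols].to_numpy(), 0.0):
            degenerate.add(cat)
            radii[cat] = rs[0]
        else:
            best = max(cols, key=lambda c: imp[c])
            radii[cat] = parse_feature_column(best)[1]
    return SelectedVariables(radii=radii, degenerate=degenerate), report


# ---------------------------------------------------------------------------
# Phase 2: hyperparameter sweep
# ---------------------------------------------------------------------------


def phase2_sweep(
    table: pd.DataFrame,
    selected: SelectedVariables,
    response: str = "no2_ppb",
    ntree_grid=PAPER_NTREE_GRID,
    mtry_grid=PAPER_MTRY_GRID,
    seeds=(0, 1, 2),
) -> tuple[LURFResults, pd.DataFrame]:
    """Sweep (ntree, mtry) x seeds; return the robust model + sweep table.

    The robust model minimises mean OOB RMSE across seeds, ties broken
    toward smaller ntree then smaller mtry, and is refit with the first
    seed.
    """
    ntree_grid = list(ntree_grid)
    mtry_grid = list(mtry_grid)
    seeds = list(seeds)
    if not ntree_grid or not mtry_grid or not seeds:
        raise ValueError("empty hyperparameter grid or seed list")
    cols = selected.columns()
    model = LURF(table[response], table[cols])
    p = len(cols)
    rows = []
    for ntree, mtry, seed in itertools.product(ntree_grid, mtry_grid, seeds):
        if mtry > p:
            continue
        res = model.fit(ntree=ntree, mtry=mtry, seed=seed)
        rows.append(
            {"ntree": ntree, "mtry": mtry, "seed": seed, "oob_rmse": res.oob_rmse()}
        )
    sweep = pd.DataFrame(rows)
    if sweep.empty:
        raise ValueError("no feasible (ntree, mtry) combination")
    mean_tbl = (
        sweep.groupby(["ntree", "mtry"], as_index=False)["oob_rmse"]
        .mean()
        .sort_values(["oob_rmse", "ntree", "mtry"], kind="stable")
        .reset_index(drop=True)
    )
    best_ntree = int(mean_tbl.loc[0, "ntree"])
    best_mtry = int(mean_tbl.loc[0, "mtry"])
    final = model.fit(ntree=best_ntree, mtry=best_mtry, seed=seeds[0])
    final.selected = selected
    final.sweep_table = sweep
    return final, sweep


# ---------------------------------------------------------------------------
# LUR baseline
# ---------------------------------------------------------------------------


class LUR:
    """Linear land-use regression baseline on the reduced predictor set."""

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog_df = exog if isinstance(exog, pd.DataFrame) else pd.DataFrame(
            np.asarray(exog, dtype=float)
        )
        if self.endog.size != len(self.exog_df):
            raise ValueError("endog/exog length mismatch")

    def fit(
        self,
        correlation_threshold: float = 0.7,
        vif_ceiling: float = 5.0,
        k: int = 6,
        max_candidates: int = 4,
        seed: int = 0,
    ) -> "LURResults":
        return fit_lur(
            self.endog,
            self.exog_df,
            correlation_threshold=correlation_threshold,
            vif_ceiling=vif_ceiling,
            k=k,
            max_candidates=max_candidates,
            seed=seed,
        )


@dataclass
class LURResults:
    """Fitted LUR: OLS estimates, diagnostics and candidate bookkeeping."""

    ols_results: object  # statsmodels RegressionResults
    included: list[str]
    vif: dict
    kfold_rmse: float
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    pruned: list[str] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.ols_results.params

    @property
    def bse(self) -> pd.Series:
        return self.ols_results.bse

    @property
    def aic(self) -> float:
        return float(self.ols_results.aic)

    def predict(self, exog) -> np.ndarray:
        X = exog[self.included] if isinstance(exog, pd.DataFrame) else pd.DataFrame(exog)
        X = sm.add_constant(X.astype(float), has_constant="add")
        return np.asarray(self.ols_results.predict(X))

    def summary(self):
        return self.ols_results.summary()


def _stepwise_aic(y, X: pd.DataFrame, max_steps: int = 100) -> list[list[str]]:
    """Bidirectional stepwise search by AIC; returns the sequence of
    improving variable sets (later = better)."""
    included: list[str] = []
    trail: list[list[str]] = []
    def aic_of(cols):
        Xc = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, Xc).fit().aic
    current = aic_of([])
    for _ in range(max_steps):
        moves = []
        for c in X.columns:
            if c not in included:
                moves.append((aic_of(included + [c]), "add", c))
        for c in included:
            cols = [v for v in included if v != c]
            moves.append((aic_of(cols), "drop", c))
        if not moves:
            break
        moves.sort(key=lambda t: t[0])
        best_aic, op, c = moves[0]
        if best_aic >= current - 1e-9:
            break
        current = best_aic
        included = included + [c] if op == "add" else [v for v in included if v != c]
        trail.append(list(included))
    return trail


def _vif_table(X: pd.DataFrame) -> dict:
    if X.shape[1] < 2:
        return {c: 1.0 for c in X.columns}
    Xc = sm.add_constant(X, has_constant="add").to_numpy(dtype=float)
    return {
        c: float(variance_inflation_factor(Xc, i + 1)) for i, c in enumerate(X.columns)
    }


def _kfold_rmse(y, X: pd.DataFrame, cols, k, seed) -> float:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    errs = []
    Xs = sm.add_constant(X[cols], has_constant="add")
    for tr, te in kf.split(Xs):
        fit = sm.OLS(y[tr], Xs.iloc[tr]).fit()
        pred = fit.predict(Xs.iloc[te])
        errs.append(np.asarray(y[te] - pred))
    return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))


def fit_lur(
    y,
    X: pd.DataFrame,
    correlation_threshold: float = 0.7,
    vif_ceiling: float = 5.0,
    k: int = 6,
    max_candidates: int = 4,
    seed: int = 0,
) -> LURResults:
    """Correlation pruning -> stepwise AIC -> VIF screen -> k-fold pick."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=float)
    X = X.astype(float)

    # correlation pruning: drop the later column of any |r| > threshold pair
    corr = X.corr().abs().to_numpy()
    cols = list(X.columns)
    keep: list[str] = []
    pruned: list[str] = []
    for i, c in enumerate(cols):
        if X[c].std() == 0:
            pruned.append(c)
            continue
        if any(corr[i, cols.index(kc)] > correlation_threshold for kc in keep):
            pruned.append(c)
        else:
            keep.append(c)
    Xk = X[keep]

    trail = _stepwise_aic(y, Xk)
    candidates = []
    for cols_i in reversed(trail):  # best-AIC first
        if not cols_i:
            continue
        vif = _vif_table(Xk[cols_i])
        if all(v <= vif_ceiling for v in vif.values()):
            candidates.append(cols_i)
        if len(candidates) >= max_candidates:
            break
    if not candidates:
        # fall back to the best single predictor by AIC
        warnings.warn("no stepwise candidate passed the VIF ceiling; "
                      "falling back to the best single-predictor model")
        best_single = min(
            Xk.columns,
            key=lambda c: sm.OLS(y, sm.add_constant(Xk[[c]], has_constant="add")).fit().aic,
        )
        candidates = [[best_single]]

    rows = []
    for cols_i in candidates:
        rows.append(
            {
                "variables": tuple(cols_i),
                "aic": sm.OLS(y, sm.add_constant(Xk[cols_i], has_constant="add")).fit().aic,
                "kfold_rmse": _kfold_rmse(y, Xk, cols_i, k, seed),
            }
        )
    cand_df = pd.DataFrame(rows).sort_values("kfold_rmse", kind="stable").reset_index(drop=True)
    final_cols = list(cand_df.loc[0, "variables"])
    fit = sm.OLS(y, sm.add_constant(Xk[final_cols], has_constant="add")).fit()
    return LURResults(
        ols_results=fit,
        included=final_cols,
        vif=_vif_table(Xk[final_cols]),
        kfold_rmse=float(cand_df.loc[0, "kfold_rmse"]),
        candidates=cand_df,
        pruned=pruned,
    )
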