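"""Category zeroing, modification rebalancing arithmetic, attribution
additivity on an additive oracle model, and scenario spatial patterns."""

import numpy as np
import pandas as pd
import pytest

from lurfkit.categories import AREAL_CATEGORIES
from lurfkit.features import buffer_area_ha
from lurfkit.geometry import point_segment_distance
from lurfkit.predict import grid_points
from lurfkit.scenarios import (
    Scenario,
    apply_modification,
    attribute_category,
    run_sensitivity,
    zero_category,
)


def pct_table(radius=500, **pcts):
    """One-location feature table with areal covers given in % of the
    buffer disc area."""
    area = buffer_area_ha(radius)
    row = {"location_id": "L0", "x": 0.0, "y": 0.0, "elevation": 0.0}
    for cat in AREAL_CATEGORIES:
        row[f"{cat}_{radius:04d}"] = pcts.get(cat, 0.0) / 100.0 * area
    row[f"vmt_freeway_{radius:04d}"] = pcts.get("vmt", 0.0)
    return pd.DataFrame([row])


def pct_of(table, col, radius=500):
    return float(table[col].iloc[0] / buffer_area_ha(radius) * 100.0)


class TestZeroCategory:
    def test_zero_touches_only_target(self, fitted_pipeline):
        gf = fitted_pipeline["grid_features"].head(50)
        out = zero_category(gf, "trees")
        tree_cols = [c for c in gf.columns if c.startswith("trees_")]
        assert (out[tree_cols].to_numpy() == 0).all()
        others = [c for c in gf.columns if c not in tree_cols]
        pd.testing.assert_frame_equal(out[others], gf[others])

    def test_idempotent_and_noop_on_zero(self):
        t = pct_table(trees=0.0, dev_high=40.0)
        once = zero_category(t, "trees")
        pd.testing.assert_frame_equal(once, t)  # already zero
        pd.testing.assert_frame_equal(zero_category(once, "trees"), once)

    def test_unknown_category_rejected(self):
        with pytest.raises(KeyError):
            zero_category(pct_table(), "wetlands")


class TestModification:
    @pytest.mark.parametrize("start,delta,expected", [
        (20.0, 10.0, 30.0),
        (20.0, 5.0, 25.0),
        (20.0, 2.0, 22.0),
        (0.0, 10.0, 10.0),
        (0.0, 5.0, 5.0),
        (0.0, 2.0, 2.0),
    ])
    def test_percentage_point_increases(self, start, delta, expected):
        """A +d% change adds d percentage points of buffer area, so cover
        rises even where there currently is none."""
        t = pct_table(trees=start, dev_high=30.0)
        out = apply_modification(t, Scenario("trees", delta=delta))
        assert pct_of(out, "trees_0500") == pytest.approx(expected, abs=1e-12)

    def test_proportional_rebalancing_hand_example(self):
        """trees 20, dev 60, open 20, +5 -> 25 / 56.25 / 18.75 (others
        scaled by 75/80); areal total preserved."""
        t = pct_table(trees=20.0, dev_high=60.0, dev_open=20.0)
        out = apply_modification(t, Scenario("trees", delta=5.0))
        assert pct_of(out, "trees_0500") == pytest.approx(25.0, abs=1e-12)
        assert pct_of(out, "dev_high_0500") == pytest.approx(56.25, abs=1e-12)
        assert pct_of(out, "dev_open_0500") == pytest.approx(18.75, abs=1e-12)
        total = sum(pct_of(out, f"{c}_0500") for c in AREAL_CATEGORIES)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_decrease_rebalances_upward(self):
        t = pct_table(trees=20.0, dev_high=40.0)
        out = apply_modification(t, Scenario("trees", delta=-10.0))
        assert pct_of(out, "trees_0500") == pytest.approx(10.0)
        assert pct_of(out, "dev_high_0500") == pytest.approx(50.0)

    def test_clamping_and_empty_pool_warns(self):
        t = pct_table(trees=95.0)
        with pytest.warns(UserWarning, match="pool empty"):
            out = apply_modification(t, Scenario("trees", delta=10.0))
        assert pct_of(out, "trees_0500") == pytest.approx(100.0)

    def test_vmt_is_multiplicative_and_unrebalanced(self):
        t = pct_table(trees=20.0, vmt=5000.0)
        out = apply_modification(t, Scenario("vmt_freeway", delta=-10.0))
        assert out["vmt_freeway_0500"].iloc[0] == pytest.approx(4500.0)
        assert pct_of(out, "trees_0500") == pytest.approx(20.0)

    def test_zero_equals_modification_to_zero_without_rebalance(self):
        t = pct_table(trees=35.0, dev_high=25.0)
        a = zero_category(t, "trees")
        b = apply_modification(t, Scenario("trees", delta=-100.0, rebalance=False))
        pd.testing.assert_frame_equal(a, b)

    def test_fractions_valid_after_modification(self, fitted_pipeline):
        """Exhaustive scan: post-modification covers in [0, 100]% and the
        per-buffer areal total <= 100% at every grid point and radius."""
        gf = fitted_pipeline["grid_features"]
        out = apply_modification(gf, Scenario("trees", delta=10.0))
        for r in (100, 500, 1200):
            area = buffer_area_ha(r)
            pcts = np.column_stack(
                [out[f"{c}_{r:04d}"].to_numpy() / area * 100.0 for c in AREAL_CATEGORIES]
            )
            assert (pcts >= -1e-9).all() and (pcts <= 100.0 + 1e-9).all()
            assert (pcts.sum(axis=1) <= 100.0 + 1e-6).all()


class AdditiveOracle:
    """predict = sum of per-category coefficients x the 500 m column."""

    def __init__(self, coefs):
        self.coefs = coefs

    def predict(self, table):
        out = np.zeros(len(table))
        for cat, c in self.coefs.items():
            out = out + c * table[f"{cat}_0500"].to_numpy()
        return out


class TestAttribution:
    EXTENT = (0.0, 0.0, 2000.0, 2000.0)

    def oracle_features(self):
        rng = np.random.default_rng(0)
        pts = grid_points(self.EXTENT, 1000.0)
        df = pts.copy()
        for cat in ("trees", "dev_high", "primary"):
            df[f"{cat}_0500"] = rng.uniform(0, 10, len(pts))
        return df

    def test_absent_category_attributes_zero(self):
        df = self.oracle_features()
        df["primary_0500"] = 0.0
        m = AdditiveOracle({"trees": -0.1, "dev_high": 0.2, "primary": 0.3})
        res = attribute_category(m, m, df, self.EXTENT, "primary", 1000.0)
        assert res.mean_delta_ppb == 0.0
        assert res.range_delta_ppb == (0.0, 0.0)

    def test_additive_oracle_attributions_sum_exactly(self):
        """For an additive model, per-category attributions sum to
        baseline minus all-zeroed, cell by cell."""
        df = self.oracle_features()
        m = AdditiveOracle({"trees": -0.1, "dev_high": 0.2, "primary": 0.3})
        total = np.zeros((2, 2))
        for cat in ("trees", "dev_high", "primary"):
            total += attribute_category(m, m, df, self.EXTENT, cat, 1000.0).delta_surface.values
        allz = df.copy()
        for cat in ("trees", "dev_high", "primary"):
            allz = zero_category(allz, cat)
        base = m.predict(df).reshape(2, 2)
        zero = m.predict(allz).reshape(2, 2)
        np.testing.assert_allclose(total, base - zero, atol=1e-12)

    def test_disjoint_footprints_additive(self):
        """Categories with disjoint footprints attribute exactly
        additively under an additive model, jointly or separately."""
        df = self.oracle_features()
        df.loc[:1, "trees_0500"] = 0.0
        df.loc[2:, "dev_high_0500"] = 0.0
        m = AdditiveOracle({"trees": -0.1, "dev_high": 0.2, "primary": 0.3})
        joint = attribute_category(m, m, df, self.EXTENT, ("trees", "dev_high"), 1000.0)
        sep = (
            attribute_category(m, m, df, self.EXTENT, "trees", 1000.0).delta_surface.values
            + attribute_category(m, m, df, self.EXTENT, "dev_high", 1000.0).delta_surface.values
        )
        np.testing.assert_allclose(joint.delta_surface.values, sep, atol=1e-12)


class TestSensitivityRuns:
    def test_empty_scenario_list(self, fitted_pipeline):
        table, surfaces = run_sensitivity(
            fitted_pipeline["models"]["summer"],
            fitted_pipeline["models"]["winter"],
            fitted_pipeline["grid_features"].head(0),
            fitted_pipeline["city"].extent,
            [],
            cell_m=fitted_pipeline["cell_m"],
            baseline=fitted_pipeline["annual_surface"],
        )
        assert len(table) == 0 and surfaces == {}

    def test_vmt_delta_local_to_freeways(self, fitted_pipeline):
        """VMT scenarios perturb NO2 only near freeways: beyond 3 decay
        lengths (900 m) the change is under 10% of the peak change."""
        fp = fitted_pipeline
        table, surfaces = run_sensitivity(
            fp["models"]["summer"], fp["models"]["winter"], fp["grid_features"],
            fp["city"].extent, [Scenario("vmt_freeway", delta=-10.0)],
            cell_m=fp["cell_m"], baseline=fp["annual_surface"],
        )
        delta = surfaces["vmt_freeway_-10%"]
        pts = grid_points(fp["city"].extent, fp["cell_m"])
        d = point_segment_distance(
            pts["x"].to_numpy(), pts["y"].to_numpy(), fp["city"].class_segments("freeway")
        ).min(axis=1).reshape(delta.values.shape)
        peak = np.abs(delta.values).max()
        assert peak > 0
        assert np.abs(delta.values[d > 900.0]).max() < 0.10 * peak

    def test_opposite_deltas_give_opposite_responses(self, fitted_pipeline):
        """+5 and -5 tree scenarios move NO2 in opposite directions: the
        study-wide mean responses are opposite-signed with comparable
        magnitude, and among cells responding strongly in both runs the
        modal joint pattern is (decrease under +5, increase under -5).

        Cell-by-cell antisymmetry is not asserted: a forest responds as
        a step function, so individual cells can respond with the same
        sign in both directions even when the aggregate response is
        cleanly antisymmetric.
        """
        fp = fitted_pipeline
        _, surfaces = run_sensitivity(
            fp["models"]["summer"], fp["models"]["winter"], fp["grid_features"],
            fp["city"].extent,
            [Scenario("trees", delta=5.0), Scenario("trees", delta=-5.0)],
            cell_m=fp["cell_m"], baseline=fp["annual_surface"],
        )
        up = surfaces["trees_+5%"].values
        dn = surfaces["trees_-5%"].values
        assert up.mean() < 0 < dn.mean()
        assert 0.5 <= -up.mean() / dn.mean() <= 2.0
        floor = 0.10 * np.percentile(np.abs(up), 95)
        both = (np.abs(up) > floor) & (np.abs(dn) > floor)
        quadrants = {
            (su, sd): ((np.sign(up[both]) == su) & (np.sign(dn[both]) == sd)).mean()
            for su in (-1, 1)
            for sd in (-1, 1)
        }
        assert max(quadrants, key=quadrants.get) == (-1, 1)
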