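"""Population allocation, log-linear health impact functions, and the
worst-quintile scope."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from lurfkit.grids import GridSurface, Raster
from lurfkit.health import (
    HealthImpactFunction,
    allocate_population,
    apply_hif,
    default_hif_registry,
    worst_quintile_mask,
)


def grid(n=4, cell=200.0):
    return Raster(np.zeros((n, n)), 0.0, 0.0, cell)


def blocks(*rows):
    return pd.DataFrame(
        {"geometry": [r[0] for r in rows], "population": [r[1] for r in rows]}
    )


class TestAllocation:
    def test_exact_cover_splits_evenly(self):
        g = grid(2)
        out = allocate_population(blocks((box(0, 0, 400, 400), 400.0)), g)
        np.testing.assert_allclose(out.values, 100.0)

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(12):
            x, y = rng.uniform(0, 600, 2)
            rows.append((box(x, y, x + rng.uniform(50, 150), y + rng.uniform(50, 150)),
                         float(rng.integers(10, 500))))
        g = grid(4)
        out = allocate_population(blocks(*rows), g)
        assert out.values.sum() == pytest.approx(sum(r[1] for r in rows), rel=1e-6)

    def test_partial_overlap_matches_fine_raster_oracle(self):
        """A polygon half-overlapping a cell contributes count x
        (overlap/polygon area), cross-checked by counting 1 m subcells."""
        g = grid(2)
        poly = box(100.0, 50.0, 300.0, 150.0)  # straddles cells
        out = allocate_population(blocks((poly, 1000.0)), g)
        xs = np.arange(0.0, 400.0, 1.0) + 0.5
        xx, yy = np.meshgrid(xs, xs)
        inside = (xx >= 100) & (xx < 300) & (yy >= 50) & (yy < 150)
        for r in range(2):
            for c in range(2):
                cell_mask = (
                    (xx >= c * 200) & (xx < (c + 1) * 200)
                    & (yy >= r * 200) & (yy < (r + 1) * 200)
                )
                brute = 1000.0 * (inside & cell_mask).sum() / inside.sum()
                assert out.values[r, c] == pytest.approx(brute, rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            allocate_population(blocks((box(0, 0, 100, 100), -5.0)), grid(2))


class TestApplyHif:
    HIF = HealthImpactFunction("asthma", "4-12", beta_per_ppb=0.01, baseline_incidence=0.1)

    def pop(self, n=2, value=1000.0):
        return Raster(np.full((n, n), value), 0.0, 0.0, 200.0)

    def surf(self, vals):
        return GridSurface(np.asarray(vals, dtype=float), 0.0, 0.0, 200.0)

    def test_closed_form(self):
        res = apply_hif(self.HIF, self.surf([[1.0, 1.0], [1.0, 1.0]]), self.pop())
        expected = 0.1 * (1.0 - np.exp(-0.01)) * 1000.0
        np.testing.assert_allclose(res.delta_cases.values, expected, rtol=1e-9)
        assert res.total_delta_cases == pytest.approx(4 * expected, rel=1e-9)

    def test_zero_delta_zero_cases(self):
        res = apply_hif(self.HIF, self.surf(np.zeros((2, 2))), self.pop())
        assert (res.delta_cases.values == 0).all()

    def test_small_signal_linearity(self):
        dc = 1e-3 / 0.01  # beta * dC = 1e-3
        res = apply_hif(self.HIF, self.surf(np.full((2, 2), dc)), self.pop())
        linear = 0.1 * 0.01 * dc * 1000.0
        np.testing.assert_allclose(res.delta_cases.values, linear, rtol=1e-3)

    def test_sign_and_monotonicity(self):
        vals = np.array([[-2.0, -0.5], [0.5, 2.0]])
        res = apply_hif(self.HIF, self.surf(vals), self.pop())
        assert (np.sign(res.delta_cases.values) == np.sign(vals)).all()
        more = apply_hif(self.HIF, self.surf(vals * 2), self.pop())
        assert (np.abs(more.delta_cases.values) >= np.abs(res.delta_cases.values)).all()

    def test_zero_population_gives_zero(self):
        pop = self.pop(value=0.0)
        res = apply_hif(self.HIF, self.surf(np.ones((2, 2))), pop)
        assert (res.delta_cases.values == 0).all()

    def test_rate_arithmetic_recomputed(self):
        rng = np.random.default_rng(3)
        dc = self.surf(rng.normal(0, 1, (4, 4)))
        pop = Raster(rng.uniform(0, 500, (4, 4)), 0.0, 0.0, 200.0)
        res = apply_hif(self.HIF, dc, pop)
        dy = 0.1 * (1 - np.exp(-0.01 * dc.values)) * pop.values
        assert res.rate_per_100k == pytest.approx(
            1e5 * dy.sum() / pop.values.sum(), rel=1e-12
        )

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            apply_hif(self.HIF, self.surf(np.ones((2, 2))), self.pop(n=3))

    def test_invalid_hif_rejected(self):
        with pytest.raises(ValueError):
            HealthImpactFunction("x", "all", np.inf, 0.1)
        with pytest.raises(ValueError):
            HealthImpactFunction("x", "all", 0.01, -0.1)


class TestWorstQuintile:
    def test_exact_fifth_masked(self):
        vals = np.arange(100, dtype=float).reshape(10, 10)
        mask = worst_quintile_mask(GridSurface(vals, 0, 0, 200.0))
        assert mask.sum() == 20

    def test_order_statistic(self):
        rng = np.random.default_rng(1)
        s = GridSurface(rng.uniform(5, 20, (10, 10)), 0, 0, 200.0)
        mask = worst_quintile_mask(s)
        assert s.values[mask].min() >= s.values[~mask].max()

    def test_constant_surface_warns_whole_area(self):
        s = GridSurface(np.full((5, 5), 3.0), 0, 0, 200.0)
        with pytest.warns(UserWarning, match="constant"):
            mask = worst_quintile_mask(s)
        assert mask.all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="5 valid cells"):
            worst_quintile_mask(GridSurface(np.ones((2, 2)), 0, 0, 200.0))


def test_default_registry_is_valid():
    for hif in default_hif_registry():
        assert hif.form == "log-linear"
        assert hif.baseline_incidence >= 0
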